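"""Published arm-level summary statistics from the OVIVA trial economic evaluation.

OVIVA (Oral Versus Intravenous Antibiotics) randomised 1,054 adults with bone or
joint infection 1:1 to intravenous or oral antibiotics for the first six weeks of
therapy and followed them for 12 months.  Participant-level data are not publicly
deposited, so this module records the *published* arm-level summaries — unit
costs, complete-case resource use, complete-case costs, per-visit EQ-5D-3L
utilities, and the base-case incremental results — which serve two purposes:

1. calibration anchors for the synthetic-trial generator (:mod:`oviva_cea.synth`),
2. inputs to the headline-arithmetic reproductions (failure risks, savings
   extrapolation, complete-case cost difference).

All money is 2015 GBP.  "Intervention period" is days 1–42 from start of
randomised therapy; "post" is days 43–365.
"""

from __future__ import annotations

VISIT_DAYS = (0, 14, 42, 120, 365)

N_PER_ARM = 527
N_TOTAL = 1054
N_DEATHS = 23

#: Primary-endpoint definitive treatment failures (events, denominator).
FAILURES = {"iv": (74, 506), "oral": (67, 509)}

#: Conservative annual number of UK post-operative bone and joint infections
#: used for the national savings extrapolation.
ANNUAL_UK_CASES = 6350

# ---------------------------------------------------------------------------
# Unit costs (2015 GBP)
# ---------------------------------------------------------------------------
UNIT_COSTS = {
    "picc_insertion": 190.0,     # PICC line insertion, per event
    "line_removal": 34.0,        # line removal, per event
    "bed_day": 296.0,            # inpatient stay, per overnight stay
    "opat_district_nurse": 58.0,         # OPAT district nurse, per hour
    "opat_inpatient_centre": 109.0,      # hospital infusion centre, per hour
    "opat_self_administer": 0.0,         # self-administration, per hour
}

#: Witnessed ratio of district-nurse to self-administering OPAT, used as the
#: weighted-average fallback rate (3/5 district nurse, 2/5 self-administration).
OPAT_WEIGHT_DISTRICT_NURSE = 0.6
OPAT_WEIGHT_SELF = 0.4

# ---------------------------------------------------------------------------
# Complete-case mean resource use per participant: {measure: {period: {arm: (mean, sd)}}}
# ---------------------------------------------------------------------------
RESOURCE_USE = {
    "n_prescriptions": {
        "intervention": {"iv": (3.53, 2.15), "oral": (3.53, 2.31)},
        "post": {"iv": (3.17, 3.08), "oral": (2.90, 3.00)},
        "total": {"iv": (6.70, 3.74), "oral": (6.43, 3.93)},
    },
    "antibiotic_days": {
        "intervention": {"iv": (38.18, 32.64), "oral": (30.47, 29.12)},
        "post": {"iv": (151.6, 181.6), "oral": (155.1, 161.2)},
        "total": {"iv": (189.8, 177.5), "oral": (185.6, 156.3)},
    },
    "n_admissions": {
        "intervention": {"iv": (1.0, 0.0), "oral": (1.0, 0.0)},
        "post": {"iv": (0.829, 1.15), "oral": (0.821, 1.11)},
        "total": {"iv": (1.83, 1.15), "oral": (1.82, 1.11)},
    },
    "inpatient_days": {
        "intervention": {"iv": (17.71, 14.83), "oral": (17.22, 18.62)},
        "post": {"iv": (8.51, 16.78), "oral": (9.13, 18.11)},
        "total": {"iv": (26.22, 24.28), "oral": (26.35, 28.47)},
    },
    "iv_therapy_days": {
        "intervention": {"iv": (40.08, 30.52), "oral": (11.86, 27.45)},
        "post": {"iv": (12.50, 34.83), "oral": (6.10, 18.49)},
        "total": {"iv": (52.58, 40.37), "oral": (17.96, 33.52)},
    },
}

#: Published complete-case difference (IV − oral) in total IV-therapy days.
IV_THERAPY_DAYS_TOTAL_DIFFERENCE = 34.62

# ---------------------------------------------------------------------------
# Complete-case unadjusted costs: {category: {period: {arm: (mean, sd)}}}
# ---------------------------------------------------------------------------
COSTS_COMPLETE_CASE = {
    "antibiotics": {
        "intervention": {"iv": (786.0, 915.0), "oral": (435.0, 569.0)},
        "post": {"iv": (1206.0, 2497.0), "oral": (772.0, 1865.0)},
        "total": {"iv": (1992.0, 2545.0), "oral": (1207.0, 2043.0)},
    },
    "inpatient": {
        "intervention": {"iv": (5239.0, 4388.0), "oral": (5093.0, 5508.0)},
        "post": {"iv": (2517.0, 4963.0), "oral": (2700.0, 5358.0)},
        "total": {"iv": (7756.0, 7183.0), "oral": (7793.0, 8420.0)},
    },
    "iv_admin": {
        "intervention": {"iv": (2950.0, 2555.0), "oral": (1231.0, 1304.0)},
        "post": {"iv": (577.0, 1566.0), "oral": (318.0, 801.0)},
        "total": {"iv": (3527.0, 2920.0), "oral": (1548.0, 1618.0)},
    },
}

#: Complete-case total cost per participant (mean, SD) by arm.
TOTAL_COST_COMPLETE_CASE = {"iv": (13275.0, 10113.0), "oral": (10549.0, 10371.0)}

# ---------------------------------------------------------------------------
# Per-visit EQ-5D-3L utilities, complete case: {arm: {day: (mean, sd)}}
# ---------------------------------------------------------------------------
UTILITY_ANCHORS = {
    "iv": {0: (0.298, 0.363), 14: (0.437, 0.304), 42: (0.513, 0.316),
           120: (0.534, 0.337), 365: (0.564, 0.339)},
    "oral": {0: (0.330, 0.379), 14: (0.421, 0.338), 42: (0.531, 0.330),
             120: (0.544, 0.354), 365: (0.576, 0.346)},
}

#: Complete-case total 12-month QALYs (mean, SD) by arm.
TOTAL_QALY_COMPLETE_CASE = {"iv": (0.558, 0.265), "oral": (0.535, 0.300)}

#: Observed proportion of EQ-5D-3L responses missing at each visit
#: (26.4% at baseline rising to 45.7% at 365 days).
EQ5D_MISSING_PROB = {0: 0.266, 14: 0.415, 42: 0.298, 120: 0.414, 365: 0.457}

#: Proportion of participants with missing resource-use records (26/1054).
RESOURCE_MISSING_PROB = 26 / 1054

# ---------------------------------------------------------------------------
# Base-case (multiple imputation) incremental results
# ---------------------------------------------------------------------------
BASE_CASE = {
    "cost_mean": {"iv": 13274.0, "oral": 10534.0},
    "cost_se": {"iv": 446.0, "oral": 453.0},
    "cost_diff": 2740.0,            # IV − oral
    "cost_diff_ci": (1488.0, 3992.0),
    "qaly_mean": {"iv": 0.537, "oral": 0.545},
    "qaly_se": {"iv": 0.013, "oral": 0.015},
    "qaly_diff": -0.007,            # IV − oral
    "qaly_diff_ci": (-0.045, 0.031),
}

#: Range of the total mean cost difference across the base case and the four
#: sensitivity scenarios.
SENSITIVITY_COST_DIFF_RANGE = (2617.0, 2887.0)
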