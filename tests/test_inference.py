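"""Incremental models, dominance classification, bootstrap plane, CEAC,
sensitivity scenarios and headline arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oviva_cea import inference, reference
from oviva_cea.inference import (annual_savings, bootstrap_ce, ceac_nmb,
                                 classify_ce, fit_cost_difference,
                                 fit_qaly_difference, risk_summary,
                                 summarize_resources, welch_difference)
from oviva_cea.synth import summary_trial


def cloud_from(dq, dc):
    return inference.BootstrapCloud(delta_qaly=np.asarray(dq, float),
                                    delta_cost=np.asarray(dc, float))


# ---------------------------------------------------------------------------
# Welch differences
# ---------------------------------------------------------------------------

def test_welch_matches_textbook_formula_on_fixture():
    x = np.array([10.0, 12.0, 9.0])
    y = np.array([7.0, 8.0, 6.5])
    diff, ci, se = welch_difference(x, y)
    # oracle: hand-computed Welch statistic and Satterthwaite df
    vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
    se_hand = np.sqrt(vx + vy)
    df_hand = (vx + vy) ** 2 / (vx ** 2 / 2 + vy ** 2 / 2)
    crit = stats.t.ppf(0.975, df_hand)
    assert diff == pytest.approx(x.mean() - y.mean())
    assert se == pytest.approx(se_hand)
    assert ci[0] == pytest.approx(diff - crit * se_hand, rel=1e-6)
    assert ci[1] == pytest.approx(diff + crit * se_hand, rel=1e-6)


def test_identical_arms_give_zero_differences(complete_trial):
    # duplicate one arm's profiles into the other under new ids
    data = complete_trial
    iv_ids = data.participants.loc[data.participants["arm"] == "iv", "id"]
    part = data.participants.copy()
    resources = {}
    for pid in iv_ids:
        resources[pid] = data.resources[pid]
        twin = pid.replace("iv", "oral")
        resources[twin] = data.resources[pid]
    part = part[part["id"].isin(resources)]
    part.loc[part["id"].str.startswith("oral"), "arm"] = "oral"
    mirrored = type(data)(participants=part, resources=resources,
                          eq5d=data.eq5d[data.eq5d["id"].isin(resources)])
    out = summarize_resources(mirrored).set_index("measure")
    assert np.allclose(out["difference"], 0.0)
    assert ((out["ci_low"] <= 0) & (out["ci_high"] >= 0)).all()


def test_summary_table_shape(small_trial):
    out = summarize_resources(small_trial)
    assert {"iv_therapy_days_total", "antibiotic_days_intervention",
            "inpatient_days_post"} <= set(out["measure"])
    assert {"iv_mean", "oral_sd", "difference", "ci_low"} <= set(out.columns)


# ---------------------------------------------------------------------------
# gamma-identity GLM
# ---------------------------------------------------------------------------

def test_glm_equals_group_mean_difference_on_fixture():
    """Oracle: on a saturated two-group design the gamma identity-link MLE
    fits the arithmetic group means."""
    cost = np.array([100.0, 150, 200, 130, 170, 900, 1100, 1000, 950, 1050])
    arm = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    fit = fit_cost_difference(cost, arm)
    oracle = cost[arm == 1].mean() - cost[arm == 0].mean()
    assert fit.estimate == pytest.approx(oracle, rel=1e-6)


def test_glm_identical_arms_zero():
    cost = np.tile([500.0, 700.0, 900.0], 2)
    arm = np.repeat([1, 0], 3)
    assert fit_cost_difference(cost, arm).estimate == pytest.approx(0.0,
                                                                    abs=1e-6)


def test_glm_rejects_nonpositive_cost_naming_participant():
    with pytest.raises(ValueError, match="index 2"):
        fit_cost_difference([100.0, 200.0, 0.0, 300.0], [1, 1, 0, 0])


def test_glm_recovers_calibrated_difference_at_trial_size():
    df = summary_trial(n_per_arm=527, seed=4)
    fit = fit_cost_difference(df["total_cost"], df["arm"])
    target = (reference.BASE_CASE["cost_mean"]["iv"]
              - reference.BASE_CASE["cost_mean"]["oral"])
    assert abs(fit.estimate - target) < 2 * fit.se


def test_qaly_fit_equals_raw_difference_without_imbalance():
    rng = np.random.default_rng(5)
    arm = np.repeat([1, 0], 50)
    q = rng.normal(0.5, 0.2, 100)
    fit = fit_qaly_difference(q, arm, np.full(100, 0.4), np.full(100, 60.0))
    raw = q[:50].mean() - q[50:].mean()
    assert fit.estimate == pytest.approx(raw, abs=1e-10)


# ---------------------------------------------------------------------------
# dominance / ICER
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dc, dq, label, icer", [
    (2740.0, -0.007, "oral_dominant", None),   # base-case pattern
    (-500.0, 0.01, "iv_dominant", None),
    (3000.0, 0.1, "icer", 30_000.0),
    (-3000.0, -0.1, "icer", 30_000.0),
    (100.0, 0.0, "oral_dominant", None),       # dominance by cost alone
    (-100.0, 0.0, "iv_dominant", None),
    (0.0, 0.0, "indeterminate", None),
])
def test_classification(dc, dq, label, icer):
    c = classify_ce(dc, dq)
    assert c.label == label
    if icer is not None:
        assert c.icer == pytest.approx(icer)


def test_classification_sign_flip_symmetry():
    rng = np.random.default_rng(6)
    flip = {"oral_dominant": "iv_dominant", "iv_dominant": "oral_dominant",
            "icer": "icer", "indeterminate": "indeterminate"}
    for _ in range(200):
        dc, dq = rng.normal(0, 1000), rng.normal(0, 0.05)
        assert classify_ce(-dc, -dq).label == flip[classify_ce(dc, dq).label]


# ---------------------------------------------------------------------------
# bootstrap plane
# ---------------------------------------------------------------------------

def test_bootstrap_requires_iterations_and_both_arms():
    df = summary_trial(n_per_arm=20, seed=1)
    with pytest.raises(ValueError, match="B"):
        bootstrap_ce(df, B=0)
    with pytest.raises(ValueError, match="oral"):
        bootstrap_ce(df[df["arm"] == "iv"], B=10)


def test_bootstrap_reproducible_and_sized():
    df = summary_trial(n_per_arm=50, seed=2)
    a = bootstrap_ce(df, B=257, seed=9)
    b = bootstrap_ce(df, B=257, seed=9)
    assert a.B == 257
    assert np.array_equal(a.delta_cost, b.delta_cost)
    assert sum(a.quadrants.values()) == pytest.approx(1.0)


def test_bootstrap_constructed_certainty():
    # every oral participant cheaper and higher-QALY than every IV one
    df = pd.DataFrame({
        "arm": ["iv"] * 10 + ["oral"] * 10,
        "total_cost": [2000.0] * 10 + [1000.0] * 10,
        "total_qaly": [0.4] * 10 + [0.6] * 10,
    })
    cloud = bootstrap_ce(df, B=500, seed=3)
    assert cloud.p_cost_saving == 1.0
    assert cloud.p_qaly_gain == 1.0
    assert cloud.quadrants["SE"] == 1.0


def test_bootstrap_identical_arms_centres_at_origin():
    rng = np.random.default_rng(8)
    vals = rng.gamma(2, 500, 200)
    qs = rng.normal(0.5, 0.1, 200)
    df = pd.DataFrame({"arm": np.repeat(["iv", "oral"], 200),
                       "total_cost": np.tile(vals, 2),
                       "total_qaly": np.tile(qs, 2)})
    cloud = bootstrap_ce(df, B=1000, seed=4)
    se_c = vals.std() / np.sqrt(200) * np.sqrt(2)
    se_q = qs.std() / np.sqrt(200) * np.sqrt(2)
    assert abs(cloud.center[1]) < 3 * se_c / np.sqrt(1)  # mean of B draws
    assert abs(cloud.center[0]) < 3 * se_q


def test_ellipse_covers_95pct_of_its_own_gaussian():
    """Oracle: fresh bivariate-normal points drawn from the fitted ellipse's
    own mean/covariance fall inside the chi-square(2) contour ~95% of the
    time."""
    rng = np.random.default_rng(10)
    cov = np.array([[4.0, 1.5], [1.5, 2.0]])
    pts = rng.multivariate_normal([1.0, -2.0], cov, size=4000)
    cloud = cloud_from(pts[:, 0], pts[:, 1])
    fresh = rng.multivariate_normal(cloud.center, cloud.covariance, 20000)
    inside = cloud.mahalanobis_sq(fresh) <= stats.chi2.ppf(0.95, 2)
    assert 0.94 < inside.mean() < 0.96


def test_ellipse_boundary_lies_on_the_contour():
    rng = np.random.default_rng(11)
    pts = rng.multivariate_normal([0, 0], [[2, 0.5], [0.5, 1]], 500)
    cloud = cloud_from(pts[:, 0], pts[:, 1])
    boundary = cloud.ellipse(0.95)
    d2 = cloud.mahalanobis_sq(boundary)
    assert np.allclose(d2, stats.chi2.ppf(0.95, 2), atol=1e-8)


def test_degenerate_cloud_ellipse_raises():
    cloud = cloud_from([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    with pytest.raises(ValueError, match="degenerate"):
        cloud.ellipse()


# ---------------------------------------------------------------------------
# CEAC / NMB
# ---------------------------------------------------------------------------

def test_ceac_limits_and_errors():
    rng = np.random.default_rng(12)
    cloud = cloud_from(rng.normal(0.01, 0.02, 2000),
                       rng.normal(-2000, 700, 2000))
    curve = ceac_nmb(cloud, [0.0, 1e9])
    assert curve["p_oral_cost_effective"].iloc[0] == pytest.approx(
        cloud.p_cost_saving)
    assert curve["p_oral_cost_effective"].iloc[-1] == pytest.approx(
        cloud.p_qaly_gain, abs=1e-3)
    with pytest.raises(ValueError, match=">= 0"):
        ceac_nmb(cloud, [-1.0])


def test_ceac_dominant_cloud_is_one_everywhere():
    cloud = cloud_from([0.01, 0.02, 0.03], [-100.0, -200.0, -300.0])
    curve = ceac_nmb(cloud, [0, 10_000, 30_000, 100_000])
    assert (curve["p_oral_cost_effective"] == 1.0).all()


def test_ceac_monotone_for_southeast_cloud():
    rng = np.random.default_rng(13)
    cloud = cloud_from(np.abs(rng.normal(0.02, 0.01, 1000)),
                       rng.normal(-1000, 800, 1000))
    curve = ceac_nmb(cloud, np.linspace(0, 60_000, 25))
    p = curve["p_oral_cost_effective"].to_numpy()
    assert (np.diff(p) >= -1e-12).all()


# ---------------------------------------------------------------------------
# headline arithmetic
# ---------------------------------------------------------------------------

def test_failure_percentages():
    rs = risk_summary(74, 506, 67, 509)
    assert rs.pct_iv == 14.6 and rs.pct_oral == 13.2
    assert rs.ci[0] < rs.risk_difference < rs.ci[1]
    assert risk_summary(0, 100, 0, 100).pct_iv == 0.0


def test_risk_summary_rejects_bad_inputs():
    with pytest.raises(ValueError):
        risk_summary(5, 0, 1, 10)
    with pytest.raises(ValueError):
        risk_summary(11, 10, 1, 10)


def test_annual_savings_product():
    assert annual_savings(2740.0, 6350) == 17_399_000.0
    assert annual_savings(0.0, 99) == 0.0
    assert annual_savings(1.0, 1) == 1.0
    with pytest.raises(ValueError):
        annual_savings(-1.0, 10)


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def test_scenarios_coincide_without_missing_data(complete_trial):
    from oviva_cea.imputation import ImputationSpec
    from oviva_cea.inference import run_sensitivity

    res = run_sensitivity(
        complete_trial, scenarios=("complete_case", "mean_imputation"),
        imp_spec=ImputationSpec(m=2, cycles=2, seed=1))
    # no missing cells: identical data reach both analyses (both use the
    # Welch difference), so the estimates agree exactly
    assert res[0].cost_diff == pytest.approx(res[1].cost_diff)
    assert res[0].qaly_diff == pytest.approx(res[1].qaly_diff)


def test_opat_scenarios_differ_only_through_fallback(small_trial):
    from oviva_cea.inference import assemble_analysis_frame

    dn = assemble_analysis_frame(small_trial, missing_fallback="district_nurse")
    sa = assemble_analysis_frame(small_trial, missing_fallback="self_administer")
    arm_of = dict(zip(small_trial.participants["id"],
                      small_trial.participants["arm"]))
    affected = {pid for pid, prof in small_trial.resources.items()
                if prof.opat_type in ("missing", "inpatient")
                and prof.iv_segments}
    merged = dn.merge(sa, on="id", suffixes=("_dn", "_sa"))
    changed = merged[(merged["total_cost_dn"] != merged["total_cost_sa"])
                     & merged["total_cost_dn"].notna()]
    assert set(changed["id"]) <= affected
    # district-nurse pricing can only raise costs relative to self-admin
    assert (merged["total_cost_dn"].fillna(0)
            >= merged["total_cost_sa"].fillna(0) - 1e-9).all()
    del arm_of


def test_unknown_scenario_rejected(small_trial):
    from oviva_cea.inference import analyse_scenario, assemble_analysis_frame

    frame = assemble_analysis_frame(small_trial)
    with pytest.raises(ValueError, match="scenario"):
        analyse_scenario(frame, "bayesian")
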