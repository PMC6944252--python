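"""Economic-evaluation core: arm summaries, incremental GLMs, ICER/dominance,
bootstrap cost-effectiveness plane, CEAC/NMB, sensitivity scenarios.

Sign conventions
----------------
Tabulated differences (resource use, costs, QALYs) are **IV minus oral**,
matching the published difference columns.  The bootstrap cloud, CE plane and
CEAC are oriented **oral minus IV** (the published plane plots the oral
strategy relative to IV), so "cost saving" means a negative cloud Δcost and a
"QALY gain" a positive cloud ΔQALY.

The incremental cost model is a gamma-family, identity-link GLM of total cost
on arm (on a two-group design its arm coefficient equals the arithmetic
difference of arm means); the incremental QALY model is gaussian/identity with
baseline utility and age as covariates.  Bootstrap uncertainty uses B
stratified (within-arm) resamples of the unadjusted, non-imputed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import costing, imputation, qaly, reference
from .costing import CATEGORIES, PERIODS

ARMS = ("iv", "oral")
DEFAULT_THRESHOLD = 30_000.0  # GBP per QALY
SCENARIOS = ("base", "complete_case", "mean_imputation",
             "opat_district_nurse", "opat_self_administer")


# ---------------------------------------------------------------------------
# Welch comparisons and resource summaries
# ---------------------------------------------------------------------------

def welch_difference(x: Sequence[float], y: Sequence[float],
                     alpha: float = 0.05):
    """Welch two-sample difference ``mean(x) − mean(y)`` with t CI and SE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(1 - alpha)
    se = float(np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)))
    return (float(x.mean() - y.mean()), (float(ci.low), float(ci.high)), se)


def resource_quantities(profile: costing.ResourceProfile) -> dict[str, float]:
    """Per-participant resource-use measures by period (day-42 boundary split):
    prescription counts, summed antibiotic days, admission counts, inpatient
    bed-days (nights) and summed IV-therapy days."""
    prof = costing.truncate_profile(profile)
    out: dict[str, float] = {}
    cut = costing.INTERVENTION_END_DAY

    def split_days(s: int, e: int) -> tuple[int, int]:
        pre = max(0, min(e, cut) - s + 1)
        return pre, (e - s + 1) - pre

    rx_pre = sum(1 for p in prof.prescriptions if p.start_day <= cut)
    abx = [split_days(p.start_day, p.end_day) for p in prof.prescriptions]
    iv = [split_days(s, e) for s, e in prof.iv_segments]
    adm_pre = sum(1 for s, _ in prof.admissions if s <= cut)
    nights = [(max(0, min(e, cut) - s), (e - s) - max(0, min(e, cut) - s))
              for s, e in prof.admissions]

    out["n_prescriptions_intervention"] = rx_pre
    out["n_prescriptions_post"] = len(prof.prescriptions) - rx_pre
    out["antibiotic_days_intervention"] = sum(a for a, _ in abx)
    out["antibiotic_days_post"] = sum(b for _, b in abx)
    out["n_admissions_intervention"] = adm_pre
    out["n_admissions_post"] = len(prof.admissions) - adm_pre
    out["inpatient_days_intervention"] = sum(a for a, _ in nights)
    out["inpatient_days_post"] = sum(b for _, b in nights)
    out["iv_therapy_days_intervention"] = sum(a for a, _ in iv)
    out["iv_therapy_days_post"] = sum(b for _, b in iv)
    for m in ("n_prescriptions", "antibiotic_days", "n_admissions",
              "inpatient_days", "iv_therapy_days"):
        out[f"{m}_total"] = out[f"{m}_intervention"] + out[f"{m}_post"]
    return out


def summarize_resources(dataset) -> pd.DataFrame:
    """Arm-comparison table of mean resource use per participant (complete
    case): per-arm mean/SD plus the Welch IV − oral difference and 95% CI."""
    arm_of = dict(zip(dataset.participants["id"], dataset.participants["arm"]))
    rows = {arm: [] for arm in ARMS}
    for pid, prof in dataset.resources.items():
        rows[arm_of[pid]].append(resource_quantities(prof))
    frames = {}
    for arm in ARMS:
        if not rows[arm]:
            raise ValueError(f"no resource records in arm {arm!r}")
        frames[arm] = pd.DataFrame(rows[arm])
    out = []
    for measure in frames["iv"].columns:
        x, y = frames["iv"][measure], frames["oral"][measure]
        diff, ci, _ = welch_difference(x, y)
        out.append({
            "measure": measure,
            "iv_mean": x.mean(), "iv_sd": x.std(ddof=1),
            "oral_mean": y.mean(), "oral_sd": y.std(ddof=1),
            "difference": diff, "ci_low": ci[0], "ci_high": ci[1],
        })
    return pd.DataFrame(out)


def cost_dataset(dataset, costs: costing.UnitCostTable | None = None,
                 missing_fallback: str = "weighted") -> pd.DataFrame:
    """Per-participant cost breakdown (one row per participant with observed
    resources; participants with missing records get all-NaN cost columns)."""
    from .synth import default_unit_costs

    costs = costs or default_unit_costs()
    rows = []
    for pid, prof in dataset.resources.items():
        bd = costing.total_cost(prof, costs, missing_fallback=missing_fallback)
        rows.append({"id": pid, **bd.as_dict()})
    cost_df = pd.DataFrame(rows)
    return dataset.participants[["id", "arm"]].merge(cost_df, on="id",
                                                     how="left")


# ---------------------------------------------------------------------------
# Incremental models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    estimate: float   # IV − oral
    se: float
    ci: tuple[float, float]
    nobs: int


def fit_cost_difference(costs: Sequence[float], arm: Sequence[str] | Sequence[int],
                        alpha: float = 0.05, tol: float = 1e-8) -> FitResult:
    """Incremental cost (IV − oral) from a gamma-family identity-link GLM.

    Costs must be strictly positive (gamma support); the offending participant
    index is named otherwise.  IRLS runs to relative tolerance ``tol``.
    """
    import statsmodels.api as sm

    y = np.asarray(costs, dtype=float)
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise ValueError(
            f"nonpositive total cost at participant index {bad[0]} "
            f"(value {y[bad[0]]!r}); gamma GLM requires positive costs")
    iv = _iv_indicator(arm)
    X = sm.add_constant(iv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Gamma(
            link=sm.families.links.Identity()))
        res = model.fit(tol=tol, maxiter=200)
    if not res.converged:
        raise RuntimeError("gamma GLM did not converge")
    ci = res.conf_int(alpha)[1]
    return FitResult(estimate=float(res.params[1]), se=float(res.bse[1]),
                     ci=(float(ci[0]), float(ci[1])), nobs=len(y))


def fit_qaly_difference(total_qalys: Sequence[float], arm,
                        baseline_utility: Sequence[float],
                        age: Sequence[float], alpha: float = 0.05) -> FitResult:
    """Incremental QALYs (IV − oral), gaussian identity link, adjusted for
    baseline utility and age."""
    est, ci, se = qaly.adjust_qaly_difference(
        total_qalys, _iv_indicator(arm), baseline_utility, age, alpha=alpha)
    return FitResult(estimate=est, se=se, ci=ci, nobs=len(np.asarray(arm)))


def _iv_indicator(arm) -> np.ndarray:
    arm = np.asarray(arm)
    if arm.dtype.kind in "OU":
        return (arm == "iv").astype(float)
    return arm.astype(float)


# ---------------------------------------------------------------------------
# ICER / dominance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEClassification:
    label: str                   # "oral_dominant" | "iv_dominant" | "icer" | "indeterminate"
    icer: float | None = None    # GBP/QALY, only when label == "icer"
    note: str = ""


def classify_ce(delta_cost: float, delta_qaly: float) -> CEClassification:
    """Classify an (IV − oral) incremental pair.

    Oral dominant: oral cheaper (Δcost > 0) and at least as effective
    (ΔQALY ≤ 0); IV dominant by symmetry.  Otherwise the ICER Δcost/ΔQALY.
    Equal-QALY cases resolve by cost alone; the all-zero case is indeterminate.
    """
    if delta_cost == 0 and delta_qaly == 0:
        return CEClassification("indeterminate",
                                note="no cost or QALY difference")
    if delta_cost > 0 and delta_qaly <= 0:
        note = "dominance by cost alone" if delta_qaly == 0 else ""
        return CEClassification("oral_dominant", note=note)
    if delta_cost < 0 and delta_qaly >= 0:
        note = "dominance by cost alone" if delta_qaly == 0 else ""
        return CEClassification("iv_dominant", note=note)
    if delta_qaly == 0:
        return CEClassification("indeterminate", note="zero QALY difference")
    return CEClassification("icer", icer=delta_cost / delta_qaly)


# ---------------------------------------------------------------------------
# Bootstrap cost-effectiveness plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapCloud:
    """B paired bootstrap differences, oriented oral − IV."""

    delta_qaly: np.ndarray
    delta_cost: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.delta_cost)

    @property
    def p_cost_saving(self) -> float:
        """Fraction of resamples in which the oral arm is cheaper."""
        return float(np.mean(self.delta_cost < 0))

    @property
    def p_qaly_gain(self) -> float:
        """Fraction of resamples in which the oral arm has higher QALYs."""
        return float(np.mean(self.delta_qaly > 0))

    @property
    def quadrants(self) -> dict[str, float]:
        dq, dc = self.delta_qaly, self.delta_cost
        return {
            "NE": float(np.mean((dq > 0) & (dc >= 0))),
            "SE": float(np.mean((dq > 0) & (dc < 0))),
            "SW": float(np.mean((dq <= 0) & (dc < 0))),
            "NW": float(np.mean((dq <= 0) & (dc >= 0))),
        }

    @property
    def center(self) -> np.ndarray:
        return np.array([self.delta_qaly.mean(), self.delta_cost.mean()])

    @property
    def covariance(self) -> np.ndarray:
        return np.cov(np.vstack([self.delta_qaly, self.delta_cost]))

    def ellipse(self, level: float = 0.95, n_points: int = 200) -> np.ndarray:
        """Boundary of the bivariate-normal confidence ellipse fitted to the
        cloud (chi-square contour), as an (n_points, 2) array."""
        cov = self.covariance
        if not np.all(np.linalg.eigvalsh(cov) > 0):
            raise ValueError("degenerate cloud: covariance is singular")
        radius = np.sqrt(stats.chi2.ppf(level, df=2))
        chol = np.linalg.cholesky(cov)
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.vstack([np.cos(theta), np.sin(theta)])
        return (self.center[:, None] + radius * chol @ circle).T

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        diff = points - self.center
        return np.einsum("ij,jk,ik->i", diff,
                         np.linalg.inv(self.covariance), diff)


def bootstrap_ce(data: pd.DataFrame, B: int = 1000, seed: int = 0,
                 threshold: float = DEFAULT_THRESHOLD) -> BootstrapCloud:
    """Nonparametric bootstrap of the unadjusted arm mean differences.

    ``data`` needs columns ``arm``, ``total_cost``, ``total_qaly`` (complete
    case, non-imputed).  Resampling is stratified within arm, preserving the
    arm sizes; each resample yields the oral − IV differences in mean cost
    and mean QALY.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    complete = data.dropna(subset=["total_cost", "total_qaly"])
    rng = np.random.default_rng(seed)
    means = {}
    for arm in ARMS:
        sub = complete[complete["arm"] == arm]
        if sub.empty:
            raise ValueError(f"no complete cases in arm {arm!r}")
        vals = sub[["total_cost", "total_qaly"]].to_numpy()
        idx = rng.integers(0, len(vals), size=(B, len(vals)))
        means[arm] = vals[idx].mean(axis=1)  # (B, 2)
    delta = means["oral"] - means["iv"]
    return BootstrapCloud(delta_qaly=delta[:, 1], delta_cost=delta[:, 0],
                          threshold=threshold, seed=seed)


def ceac_nmb(cloud: BootstrapCloud,
             thresholds: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the oral strategy.

    For each willingness-to-pay λ, the probability (over bootstrap resamples)
    that the oral strategy's net monetary benefit λ·ΔQALY − Δcost is positive,
    plus the mean NMB.  At λ = 0 this equals ``p_cost_saving``; as λ → ∞ it
    tends to ``p_qaly_gain``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0):
        raise ValueError("willingness-to-pay thresholds must be >= 0")
    rows = []
    for lam in thresholds:
        nmb = lam * cloud.delta_qaly - cloud.delta_cost
        rows.append({"threshold": lam,
                     "p_oral_cost_effective": float(np.mean(nmb > 0)),
                     "mean_nmb": float(nmb.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Headline arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskSummary:
    pct_iv: float
    pct_oral: float
    risk_difference: float          # oral − IV, percentage points
    ci: tuple[float, float]


def risk_summary(failures_iv: int, n_iv: int, failures_oral: int,
                 n_oral: int, alpha: float = 0.05) -> RiskSummary:
    """Arm failure percentages (1 d.p.) and the unadjusted Wald risk
    difference (oral − IV) in percentage points."""
    for f, n in ((failures_iv, n_iv), (failures_oral, n_oral)):
        if n <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= f <= n:
            raise ValueError("failures must lie in [0, n]")
    p_iv = failures_iv / n_iv
    p_oral = failures_oral / n_oral
    se = np.sqrt(p_iv * (1 - p_iv) / n_iv + p_oral * (1 - p_oral) / n_oral)
    z = stats.norm.ppf(1 - alpha / 2)
    diff = p_oral - p_iv
    return RiskSummary(
        pct_iv=round(100 * p_iv, 1), pct_oral=round(100 * p_oral, 1),
        risk_difference=100 * diff,
        ci=(100 * (diff - z * se), 100 * (diff + z * se)))


def annual_savings(per_patient_saving: float, annual_cases: int) -> float:
    """National savings extrapolation: per-patient saving × annual case load."""
    if per_patient_saving < 0 or annual_cases < 0:
        raise ValueError("inputs must be nonnegative")
    return per_patient_saving * annual_cases


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncrementalResult:
    scenario: str
    cost_mean: Mapping[str, float]
    cost_se: Mapping[str, float]
    cost_diff: float
    cost_ci: tuple[float, float]
    qaly_mean: Mapping[str, float]
    qaly_se: Mapping[str, float]
    qaly_diff: float
    qaly_ci: tuple[float, float]
    classification: CEClassification = field(default=None)

    def __post_init__(self):
        if self.classification is None:
            object.__setattr__(self, "classification",
                               classify_ce(self.cost_diff, self.qaly_diff))

    @property
    def icer_label(self) -> str:
        c = self.classification
        return {"oral_dominant": "oral antibiotics dominant",
                "iv_dominant": "IV antibiotics dominant",
                "icer": f"{c.icer:,.0f} GBP/QALY" if c.icer is not None else "",
                "indeterminate": "indeterminate"}[c.label]

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "iv_cost_mean": self.cost_mean["iv"],
            "iv_cost_se": self.cost_se["iv"],
            "oral_cost_mean": self.cost_mean["oral"],
            "oral_cost_se": self.cost_se["oral"],
            "cost_diff": self.cost_diff,
            "cost_ci_low": self.cost_ci[0], "cost_ci_high": self.cost_ci[1],
            "iv_qaly_mean": self.qaly_mean["iv"],
            "iv_qaly_se": self.qaly_se["iv"],
            "oral_qaly_mean": self.qaly_mean["oral"],
            "oral_qaly_se": self.qaly_se["oral"],
            "qaly_diff": self.qaly_diff,
            "qaly_ci_low": self.qaly_ci[0], "qaly_ci_high": self.qaly_ci[1],
            "icer": self.icer_label,
        }


def _arm_moments(df: pd.DataFrame, col: str) -> tuple[dict, dict]:
    means, ses = {}, {}
    for arm in ARMS:
        v = df.loc[df["arm"] == arm, col].dropna()
        means[arm] = float(v.mean())
        ses[arm] = float(v.std(ddof=1) / np.sqrt(len(v)))
    return means, ses


def _pooled_arm_moments(datasets: Sequence[pd.DataFrame],
                        col: str) -> tuple[dict, dict]:
    """Arm means averaged over imputations; SEs Rubin-pooled."""
    means = {arm: [] for arm in ARMS}
    ses = {arm: [] for arm in ARMS}
    for d in datasets:
        m, s = _arm_moments(d, col)
        for arm in ARMS:
            means[arm].append(m[arm])
            ses[arm].append(s[arm])
    out_m, out_s = {}, {}
    for arm in ARMS:
        if len(datasets) >= 2:
            pe = imputation.pool_rubin(means[arm],
                                       np.square(ses[arm]))
            out_m[arm], out_s[arm] = pe.estimate, pe.se
        else:
            out_m[arm], out_s[arm] = means[arm][0], ses[arm][0]
    return out_m, out_s


def analyse_scenario(analysis_df: pd.DataFrame, scenario: str,
                     imp_spec: imputation.ImputationSpec | None = None,
                     alpha: float = 0.05) -> IncrementalResult:
    """One incremental cost-effectiveness analysis on an assembled
    participant-level frame.

    ``analysis_df`` has one row per participant with columns ``arm``, ``age``,
    ``sex``, ``u_0`` … ``u_365`` (NaN where missing), ``total_cost`` (NaN where
    the resource record is missing) and must already be costed under the
    scenario's OPAT fallback.  The scenario chooses the missing-data route:
    MICE for the base case and the OPAT scenarios, complete case or within-arm
    mean imputation for the other two.  The cost difference comes from the
    gamma identity-link GLM (base case) or the per-imputation Welch t-test
    Rubin-pooled (sensitivity scenarios, matching the trial's analysis plan);
    the QALY difference is always the covariate-adjusted gaussian model.
    """
    imp_spec = imp_spec or imputation.ImputationSpec()
    ucols = [f"u_{d}" for d in qaly.VISIT_DAYS]
    impute_cols = ucols + ["total_cost"]

    work = analysis_df.copy()
    work["arm_iv"] = _iv_indicator(work["arm"].to_numpy())

    method = {"base": "mice", "complete_case": "complete_case",
              "mean_imputation": "mean",
              "opat_district_nurse": "mice",
              "opat_self_administer": "mice"}.get(scenario)
    if method is None:
        raise ValueError(f"unknown scenario {scenario!r}")
    spec = imputation.ImputationSpec(
        method=method, m=imp_spec.m, cycles=imp_spec.cycles,
        seed=imp_spec.seed, k_pmm=imp_spec.k_pmm)

    numeric = work[["arm_iv", "age", "sex"] + impute_cols]
    completed = imputation.impute(numeric, spec, columns=impute_cols,
                                  by="arm_iv")

    death_days = analysis_df["death_day"]

    def qaly_col(d: pd.DataFrame) -> pd.DataFrame:
        d = d.copy()
        death = death_days.reindex(d.index)
        totals = []
        for idx in d.index:
            utilities = {day: float(d.at[idx, f"u_{day}"])
                         for day in qaly.VISIT_DAYS}
            dd = death.loc[idx]
            dd = None if pd.isna(dd) else int(dd)
            traj = qaly.build_trajectory(utilities, death_day=dd)
            totals.append(qaly.compute_qalys(traj).total_qaly)
        d["total_qaly"] = totals
        d["arm"] = np.where(d["arm_iv"] == 1, "iv", "oral")
        return d

    completed = [qaly_col(d) for d in completed]

    # cost difference
    if scenario == "base":
        pooled_cost = imputation.pooled_fit(
            completed,
            lambda d: (lambda r: (r.estimate, r.se))(
                fit_cost_difference(d["total_cost"], d["arm_iv"])),
            alpha=alpha)
    else:
        pooled_cost = imputation.pooled_fit(
            completed,
            lambda d: (lambda r: (r[0], r[2]))(
                welch_difference(d.loc[d["arm_iv"] == 1, "total_cost"],
                                 d.loc[d["arm_iv"] == 0, "total_cost"])),
            alpha=alpha)
    pooled_qaly = imputation.pooled_fit(
        completed,
        lambda d: (lambda r: (r.estimate, r.se))(
            fit_qaly_difference(d["total_qaly"], d["arm_iv"], d["u_0"],
                                d["age"])),
        alpha=alpha)

    cost_mean, cost_se = _pooled_arm_moments(completed, "total_cost")
    qaly_mean, qaly_se = _pooled_arm_moments(completed, "total_qaly")
    return IncrementalResult(
        scenario=scenario,
        cost_mean=cost_mean, cost_se=cost_se,
        cost_diff=pooled_cost.estimate, cost_ci=pooled_cost.ci,
        qaly_mean=qaly_mean, qaly_se=qaly_se,
        qaly_diff=pooled_qaly.estimate, qaly_ci=pooled_qaly.ci,
    )


def run_sensitivity(dataset, scenarios: Sequence[str] = SCENARIOS,
                    costs: costing.UnitCostTable | None = None,
                    imp_spec: imputation.ImputationSpec | None = None,
                    ) -> list[IncrementalResult]:
    """Run the base case plus sensitivity scenarios on a raw trial dataset.

    The two OPAT scenarios re-run the costing stage with the corresponding
    fallback rate before repeating the base-case analysis.
    """
    results = []
    for scenario in scenarios:
        fallback = {"opat_district_nurse": "district_nurse",
                    "opat_self_administer": "self_administer"
                    }.get(scenario, "weighted")
        frame = assemble_analysis_frame(dataset, costs=costs,
                                        missing_fallback=fallback)
        results.append(analyse_scenario(frame, scenario, imp_spec=imp_spec))
    return results


def assemble_analysis_frame(dataset, costs: costing.UnitCostTable | None = None,
                            missing_fallback: str = "weighted") -> pd.DataFrame:
    """One row per participant: arm, age, sex, death_day, per-visit utilities
    (NaN where missing) and total cost (NaN where resources are missing)."""
    util = dataset.utilities_wide()
    cost = cost_dataset(dataset, costs=costs,
                        missing_fallback=missing_fallback)
    return util.merge(cost[["id", "total_cost"]], on="id", how="left")
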