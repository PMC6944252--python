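"""Missing-data handling: mean imputation, chained-equation MI, Rubin pooling.

Missing total costs are imputed at the aggregate per-participant level and
missing utilities at the utility-score level per visit, by multiple imputation
by chained equations (MICE) under a missing-at-random assumption, using
predictive mean matching (5 donors by default) so imputed values always lie in
the observed range.  Estimates from the ``m`` completed datasets are pooled
with Rubin's rules: pooled estimate = mean; total variance
``T = W̄ + (1 + 1/m) B``; interval from a t reference with the
Barnard–Rubin-style degrees of freedom ``(m − 1)(1 + W̄ / ((1 + 1/m) B))²``.

The chained-equation engine is ``statsmodels.imputation.mice.MICEData``; it
draws from NumPy's global random state, so each chain is run under an explicit
derived seed for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("complete_case", "mean", "mice")


@dataclass(frozen=True)
class ImputationSpec:
    method: str = "mice"
    m: int = 20            # number of imputed datasets
    cycles: int = 10       # chained-equation sweeps per dataset
    seed: int = 0
    k_pmm: int = 5         # predictive-mean-matching donor count
    predictors: tuple[str, ...] | None = None  # None = all other columns

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.method == "mice" and self.m < 2:
            raise ValueError("mice requires m >= 2")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")


def mean_impute(df: pd.DataFrame, columns: Sequence[str],
                by: str | None = "arm") -> pd.DataFrame:
    """Replace missing cells with the observed arithmetic mean, within arm.

    Raises if a column has no observed value in some group.
    """
    out = df.copy()
    groups = [("", out)] if by is None else out.groupby(by, sort=False)
    for key, g in groups:
        for col in columns:
            obs = g[col].dropna()
            if g[col].isna().any():
                if obs.empty:
                    raise ValueError(
                        f"cannot mean-impute {col!r}: no observed values"
                        + (f" in group {key!r}" if by else ""))
                out.loc[g.index[g[col].isna()], col] = obs.mean()
    return out


def mice_impute(df: pd.DataFrame, spec: ImputationSpec,
                columns: Sequence[str] | None = None) -> list[pd.DataFrame]:
    """Multiply impute ``df`` by chained equations with PMM.

    ``columns`` restricts which variables may *contain* missing values (all
    numeric columns act as predictors).  Returns ``m`` completed copies; each
    chain runs ``cycles`` sweeps from an independent derived seed, so the call
    is deterministic given ``spec.seed``.  Non-numeric columns pass through
    unchanged (they must be complete).
    """
    from statsmodels.imputation.mice import MICEData

    work = df.select_dtypes(include=[np.number]).copy()
    if spec.predictors is not None:
        keep = set(spec.predictors) | set(
            c for c in work.columns if work[c].isna().any())
        work = work[[c for c in work.columns if c in keep]]
    if columns is not None:
        bad = [c for c in work.columns if work[c].isna().any()
               and c not in columns]
        if bad:
            raise ValueError(f"missing values outside imputation columns: {bad}")
    passthrough = df[[c for c in df.columns if c not in work.columns]]
    if passthrough.isna().any().any():
        raise ValueError("non-imputed columns must be complete")
    if not np.isfinite(work.dropna().to_numpy()).all():
        raise ValueError("non-finite values in predictors")

    if not work.isna().any().any():
        return [df.copy() for _ in range(spec.m)]

    completed = []
    ss = np.random.SeedSequence(spec.seed)
    for child in ss.spawn(spec.m):
        np.random.seed(int(child.generate_state(1)[0] % (2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imp = MICEData(work, perturbation_method="gaussian",
                           k_pmm=spec.k_pmm)
            imp.update_all(spec.cycles)
        filled = df.copy()
        filled[imp.data.columns] = imp.data.to_numpy()
        completed.append(filled)
    return completed


def impute(df: pd.DataFrame, spec: ImputationSpec,
           columns: Sequence[str] | None = None,
           by: str | None = "arm") -> list[pd.DataFrame]:
    """Dispatch on ``spec.method``; always returns a list of completed
    datasets (length 1 except for MICE)."""
    cols = list(columns) if columns is not None else [
        c for c in df.columns if df[c].isna().any()]
    if spec.method == "complete_case":
        return [df.dropna(subset=cols)]  # original index kept for re-alignment
    if spec.method == "mean":
        return [mean_impute(df, cols, by=by)]
    return mice_impute(df, spec, columns=cols)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of ``m`` complete-data estimates."""

    estimate: float
    within_variance: float      # W̄, mean complete-data variance
    between_variance: float     # B, variance of the estimates
    m: int
    ci: tuple[float, float] = field(default=(np.nan, np.nan))
    df: float = field(default=np.inf)

    @property
    def total_variance(self) -> float:
        return self.within_variance + (1 + 1 / self.m) * self.between_variance

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               alpha: float = 0.05) -> PooledEstimate:
    """Pool per-imputation estimates and their squared standard errors."""
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    m = len(estimates)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 estimates")
    if len(variances) != m:
        raise ValueError("estimates and variances must have equal length")
    q = float(estimates.mean())
    w = float(variances.mean())
    b = float(estimates.var(ddof=1))
    t = w + (1 + 1 / m) * b
    if b > 0 and w > 0:
        r = (1 + 1 / m) * b / w
        dof = (m - 1) * (1 + 1 / r) ** 2
        crit = stats.t.ppf(1 - alpha / 2, dof)
    else:  # no between-imputation variance: normal reference
        dof = np.inf
        crit = stats.norm.ppf(1 - alpha / 2)
    half = crit * np.sqrt(t)
    return PooledEstimate(estimate=q, within_variance=w, between_variance=b,
                          m=m, ci=(q - half, q + half), df=float(dof))


def pooled_fit(datasets: Sequence[pd.DataFrame],
               fit: Callable[[pd.DataFrame], tuple[float, float]],
               alpha: float = 0.05) -> PooledEstimate:
    """Apply ``fit`` (returning ``(estimate, se)``) to each completed dataset
    and Rubin-pool.  With a single dataset, returns its estimate directly."""
    results = [fit(d) for d in datasets]
    if len(results) == 1:
        est, se = results[0]
        half = stats.norm.ppf(1 - alpha / 2) * se
        return PooledEstimate(estimate=est, within_variance=se ** 2,
                              between_variance=0.0, m=1,
                              ci=(est - half, est + half))
    return pool_rubin([r[0] for r in results], [r[1] ** 2 for r in results],
                      alpha=alpha)
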