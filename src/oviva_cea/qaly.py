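"""EQ-5D-3L scoring (UK TTO tariff), utility trajectories, and AUC QALYs.

The UK tariff is the time-trade-off value set estimated by the Measurement and
Valuation of Health study: a state scores 1 minus a constant 0.081 if any
dimension is above level 1, minus per-dimension decrements, minus a further
0.269 if any dimension is at level 3.  Full health (11111) scores exactly 1 and
the worst state (33333) scores −0.594.

QALYs are standard area under the utility curve over the 12-month horizon:
linear interpolation between the scheduled visits (days 0, 14, 42, 120, 365),
each interval contributing ``(u1 + u2)/2 × (d2 − d1)/365`` years.  Participants
who die score zero utility thereafter; the default convention interpolates
linearly from the last pre-death visit down to zero at the death day (the
alternative — zero only from the next scheduled visit — is available via
``death_interpolation="next_visit"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import reference

VISIT_DAYS = reference.VISIT_DAYS
DIMENSIONS = ("mobility", "self_care", "usual_activities",
              "pain_discomfort", "anxiety_depression")

#: UK TTO value-set decrements: {dimension: (level-2, level-3)}.
TARIFF_DECREMENTS = {
    "mobility": (0.069, 0.314),
    "self_care": (0.104, 0.214),
    "usual_activities": (0.036, 0.094),
    "pain_discomfort": (0.123, 0.386),
    "anxiety_depression": (0.071, 0.236),
}
TARIFF_ANY_DYSFUNCTION = 0.081
TARIFF_N3 = 0.269

UTILITY_FLOOR = -0.594  # score of state 33333 under the UK tariff


@dataclass(frozen=True)
class EQ5DResponse:
    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise ValueError(f"{dim} level {level!r} out of range 1-3")

    @classmethod
    def from_state(cls, state: str | Sequence[int]) -> "EQ5DResponse":
        """Build from a five-character state like ``"21111"`` or a level tuple."""
        levels = [int(c) for c in state]
        if len(levels) != 5:
            raise ValueError(f"need 5 levels, got {state!r}")
        return cls(*levels)

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(getattr(self, d) for d in DIMENSIONS)


def score_eq5d(response: EQ5DResponse | str | Sequence[int],
               decrements: Mapping[str, tuple[float, float]] | None = None) -> float:
    """UK tariff utility of an EQ-5D-3L state.

    A different three-level value set can be supplied via ``decrements``
    (same shape as :data:`TARIFF_DECREMENTS`).
    """
    if not isinstance(response, EQ5DResponse):
        response = EQ5DResponse.from_state(response)
    dec = TARIFF_DECREMENTS if decrements is None else decrements
    levels = response.levels
    u = 1.0
    if any(l > 1 for l in levels):
        u -= TARIFF_ANY_DYSFUNCTION
    for dim, level in zip(DIMENSIONS, levels):
        if level > 1:
            u -= dec[dim][level - 2]
    if any(l == 3 for l in levels):
        u -= TARIFF_N3
    return u


def all_states_scored() -> dict[tuple[int, ...], float]:
    """Tariff score of every one of the 243 EQ-5D-3L states."""
    out = {}
    for m in (1, 2, 3):
        for s in (1, 2, 3):
            for a in (1, 2, 3):
                for p in (1, 2, 3):
                    for x in (1, 2, 3):
                        levels = (m, s, a, p, x)
                        out[levels] = score_eq5d(EQ5DResponse(*levels))
    return out


class MissingUtilityError(ValueError):
    """A QALY was requested from an incomplete trajectory (impute first)."""


@dataclass(frozen=True)
class UtilityTrajectory:
    """Utilities at the scheduled visits; ``None`` marks a missing response."""

    utilities: Mapping[int, float | None]
    death_day: int | None = None

    def utility(self, day: int) -> float | None:
        return self.utilities.get(day)

    @property
    def is_complete(self) -> bool:
        return all(self.utilities.get(d) is not None for d in VISIT_DAYS)


def build_trajectory(utilities: Mapping[int, float | None],
                     death_day: int | None = None) -> UtilityTrajectory:
    """Assemble a trajectory, forcing zero utility at visits after death.

    Missing cells (absent or ``None``) stay missing — imputation is a separate
    stage and never happens here.
    """
    vals: dict[int, float | None] = {}
    for day in VISIT_DAYS:
        if death_day is not None and day > death_day:
            vals[day] = 0.0
        else:
            vals[day] = utilities.get(day)
    return UtilityTrajectory(utilities=vals, death_day=death_day)


@dataclass(frozen=True)
class QalyResult:
    interval_qalys: Mapping[tuple[int, int], float]
    total_qaly: float = field(default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "total_qaly", sum(self.interval_qalys.values()))


def compute_qalys(trajectory: UtilityTrajectory,
                  death_interpolation: str = "death_day") -> QalyResult:
    """Trapezoid AUC QALYs per inter-visit interval and in total (years).

    ``death_interpolation="death_day"`` (default): in the interval containing
    the death, utility declines linearly from the last pre-death visit to zero
    at the death day and stays zero.  ``"next_visit"``: the zeroed post-death
    visit values are interpolated as-is (utility reaches zero at the next
    scheduled visit).
    """
    if death_interpolation not in ("death_day", "next_visit"):
        raise ValueError(f"unknown death_interpolation {death_interpolation!r}")
    missing = [d for d in VISIT_DAYS if trajectory.utility(d) is None]
    if missing:
        raise MissingUtilityError(
            f"utilities missing at days {missing}; impute before computing QALYs")

    death = trajectory.death_day
    intervals: dict[tuple[int, int], float] = {}
    for d1, d2 in zip(VISIT_DAYS[:-1], VISIT_DAYS[1:]):
        u1 = trajectory.utility(d1)
        u2 = trajectory.utility(d2)
        if (death_interpolation == "death_day" and death is not None
                and d1 < death < d2):
            # triangle from (d1, u1) down to (death, 0), flat zero after
            q = u1 / 2.0 * (death - d1) / 365.0
        elif death is not None and death <= d1:
            q = 0.0
        else:
            q = (u1 + u2) / 2.0 * (d2 - d1) / 365.0
        intervals[(d1, d2)] = q
    return QalyResult(interval_qalys=intervals)


def adjust_qaly_difference(total_qalys: Sequence[float], arm: Sequence[int],
                           baseline_utility: Sequence[float],
                           age: Sequence[float], alpha: float = 0.05):
    """Baseline-adjusted QALY difference between arms.

    Fits the linear model ``QALY ~ arm + baseline_utility + age`` (identity
    link, gaussian error) and returns ``(difference, (ci_low, ci_high), se)``
    for the arm coefficient, where arm is coded 1 = IV, 0 = oral so the
    difference is IV − oral.
    """
    import numpy as np
    import statsmodels.api as sm

    arm = np.asarray(arm, dtype=float)
    if len(np.unique(arm)) < 2:
        raise ValueError("degenerate design: both arms are required")
    covariates = [np.asarray(baseline_utility, dtype=float),
                  np.asarray(age, dtype=float)]
    # constant covariates are absorbed by the intercept; keep the design
    # full rank so the arm coefficient stays identified
    covariates = [c for c in covariates if np.ptp(c) > 0]
    X = sm.add_constant(np.column_stack([arm] + covariates))
    res = sm.OLS(np.asarray(total_qalys, dtype=float), X).fit()
    ci = res.conf_int(alpha)[1]
    return float(res.params[1]), (float(ci[0]), float(ci[1])), float(res.bse[1])
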