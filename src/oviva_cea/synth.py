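"""Synthetic OVIVA-like trial data, calibrated to published arm-level summaries.

Real participant-level data from the trial are not publicly deposited, so this
module generates datasets with the statistical structure the downstream
analysis assumes: two balanced arms, right-skewed resource durations (gamma),
longitudinally correlated EQ-5D-3L responses (latent AR(1) thresholded onto the
tariff grid), deaths that truncate events and zero utilities, missing-at-random
questionnaire responses, and whole-participant missing resource records.

The dataclass defaults *are* the OVIVA preset: per-arm resource-duration means
and SDs from the published complete-case resource table, per-visit utility
means and SDs from the published utility table, the observed per-visit EQ-5D
missingness proportions, 23/1054 deaths, and 26/1054 missing resource records.

Utilities are generated on the EQ-5D level scale: a latent standard-normal
AR(1) draw per visit is mapped to a target utility (mean-corrected for
censoring at the tariff range [−0.594, 1]) and then stochastically rounded to
the two adjacent scores on the 3-level tariff grid, so the *expected* scored
utility equals the configured anchor exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import reference
from .costing import Prescription, ResourceProfile, UnitCostTable
from .qaly import UTILITY_FLOOR, all_states_scored, score_eq5d

VISIT_DAYS = reference.VISIT_DAYS
ARMS = ("iv", "oral")
HORIZON = 365
INTERVENTION_END = 42

#: Synthetic antibiotic price list (GBP per day).  The three agents and their
#: prices reproduce the published blended cost-per-antibiotic-day in each
#: arm × period when combined with the route mixes in the arm parameters.
DEFAULT_DRUG_PRICES = {
    "iv_agent": 24.90,
    "oral_combination": 18.00,
    "oral_standard": 4.50,
}

SURGICAL_CATEGORIES = (
    ("debridement_no_implant", 0.306),
    ("no_debridement_no_implant", 0.051),
    ("debridement_implant_retained", 0.234),
    ("metalware_removed", 0.158),
    ("prosthesis_removed", 0.128),
    ("prosthesis_one_stage_revision", 0.085),
    ("spinal_debridement", 0.012),
    ("spinal_no_debridement", 0.025),
)


class ConfigurationError(ValueError):
    """Invalid synthetic-trial configuration."""


def default_unit_costs(inflation_multiplier: float = 1.0) -> UnitCostTable:
    """Trial unit costs plus the synthetic antibiotic price list."""
    return UnitCostTable(antibiotic_daily_cost=dict(DEFAULT_DRUG_PRICES),
                         inflation_multiplier=inflation_multiplier)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmResourceParams:
    """Per-arm resource-use generating parameters.

    Durations are (mean, sd) of the *marginal* per-participant distribution;
    IV therapy additionally has a probability of any use, with the conditional
    gamma parameters solved from the marginal moments.  ``iv_route_frac`` is
    the fraction of antibiotic days on the IV-route agent, ``combo_frac`` the
    fraction of the remaining oral days on the combination (higher-priced)
    agent, per period.
    """

    iv_any: Mapping[str, float]                  # {'intervention': p, 'post': p}
    iv_days: Mapping[str, tuple[float, float]]   # marginal (mean, sd)
    abx_days: Mapping[str, tuple[float, float]]
    n_rx: Mapping[str, float]                    # mean prescription count (>=1)
    iv_route_frac: Mapping[str, float]
    combo_frac: Mapping[str, float]
    first_los: tuple[float, float]               # nights of the initial admission
    post_admission_rate: float                   # Poisson mean
    post_los_each: tuple[float, float]           # nights per later admission


def _iv_arm_params() -> ArmResourceParams:
    r = reference.RESOURCE_USE
    return ArmResourceParams(
        iv_any={"intervention": 1.0, "post": 0.25},
        iv_days={"intervention": r["iv_therapy_days"]["intervention"]["iv"],
                 "post": r["iv_therapy_days"]["post"]["iv"]},
        abx_days={"intervention": r["antibiotic_days"]["intervention"]["iv"],
                  "post": r["antibiotic_days"]["post"]["iv"]},
        n_rx={"intervention": r["n_prescriptions"]["intervention"]["iv"][0],
              "post": r["n_prescriptions"]["post"]["iv"][0]},
        iv_route_frac={"intervention": 0.75, "post": 0.08},
        combo_frac={"intervention": 0.24, "post": 0.15},
        first_los=r["inpatient_days"]["intervention"]["iv"],
        post_admission_rate=r["n_admissions"]["post"]["iv"][0],
        post_los_each=(r["inpatient_days"]["post"]["iv"][0]
                       / r["n_admissions"]["post"]["iv"][0], 12.0),
    )


def _oral_arm_params() -> ArmResourceParams:
    r = reference.RESOURCE_USE
    return ArmResourceParams(
        iv_any={"intervention": 0.30, "post": 0.18},
        iv_days={"intervention": r["iv_therapy_days"]["intervention"]["oral"],
                 "post": r["iv_therapy_days"]["post"]["oral"]},
        abx_days={"intervention": r["antibiotic_days"]["intervention"]["oral"],
                  "post": r["antibiotic_days"]["post"]["oral"]},
        n_rx={"intervention": r["n_prescriptions"]["intervention"]["oral"][0],
              "post": r["n_prescriptions"]["post"]["oral"][0]},
        iv_route_frac={"intervention": 0.10, "post": 0.04},
        combo_frac={"intervention": 0.64, "post": 0.0},
        first_los=r["inpatient_days"]["intervention"]["oral"],
        post_admission_rate=r["n_admissions"]["post"]["oral"][0],
        post_los_each=(r["inpatient_days"]["post"]["oral"][0]
                       / r["n_admissions"]["post"]["oral"][0], 12.0),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-trial configuration.  Defaults are the OVIVA preset."""

    n_per_arm: int = reference.N_PER_ARM
    seed: int = 0
    arm_effects: Mapping[str, ArmResourceParams] = field(
        default_factory=lambda: {"iv": _iv_arm_params(), "oral": _oral_arm_params()})
    utility_anchors: Mapping[str, Mapping[int, tuple[float, float]]] = field(
        default_factory=lambda: {a: dict(v) for a, v in
                                 reference.UTILITY_ANCHORS.items()})
    utility_rho: float = 0.6       # latent AR(1) correlation between visits
    missing_prob: Mapping[int, float] = field(
        default_factory=lambda: dict(reference.EQ5D_MISSING_PROB))
    mar_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"arm": 0.2, "age_per_decade": 0.15,
                                 "prior_utility": -0.8, "propensity_sd": 2.5})
    resource_missing_prob: float = reference.RESOURCE_MISSING_PROB
    death_prob: float = reference.N_DEATHS / reference.N_TOTAL
    opat_mix: Mapping[str, float] = field(
        default_factory=lambda: {"district_nurse": 0.42, "inpatient": 0.20,
                                 "self_administer": 0.28, "missing": 0.10})
    male_prob: float = 0.643
    age_mean: float = 59.5
    age_sd: float = 14.5
    age_range: tuple[int, int] = (18, 92)

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ConfigurationError("n_per_arm must be >= 2")
        probs = {"resource_missing_prob": self.resource_missing_prob,
                 "death_prob": self.death_prob, "male_prob": self.male_prob}
        probs.update({f"missing_prob[{d}]": p for d, p in self.missing_prob.items()})
        probs.update({f"opat_mix[{k}]": v for k, v in self.opat_mix.items()})
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} = {p} outside [0, 1]")
        if abs(sum(self.opat_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("opat_mix must sum to 1")
        if not -1.0 < self.utility_rho < 1.0:
            raise ConfigurationError("utility_rho must be in (-1, 1)")

    def replace(self, **kw) -> "SynthConfig":
        return dc_replace(self, **kw)

    @classmethod
    def oviva(cls, **overrides) -> "SynthConfig":
        """The preset calibrated to the published trial summaries."""
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        """Load a configuration from a plain key/value YAML file.

        Only scalar fields and the plain-mapping fields (missing_prob,
        opat_mix, mar_coefficients, utility_anchors) may be overridden; keys
        absent from the file keep their preset values.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key, value in raw.items():
            if key == "missing_prob":
                kw[key] = {int(k): float(v) for k, v in value.items()}
            elif key == "utility_anchors":
                kw[key] = {arm: {int(d): tuple(mv) for d, mv in per.items()}
                           for arm, per in value.items()}
            elif key == "age_range":
                kw[key] = tuple(value)
            else:
                kw[key] = value
        return cls(**kw)


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

EQ5D_COLUMNS = ["mobility", "self_care", "usual_activities",
                "pain_discomfort", "anxiety_depression"]


@dataclass
class TrialDataset:
    """Participants, their resource profiles, and EQ-5D-3L responses.

    ``resources`` omits participants whose resource record is missing;
    ``eq5d`` has one row per *observed* (participant, visit) response.
    """

    participants: pd.DataFrame
    resources: dict[str, ResourceProfile]
    eq5d: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.participants["id"])
        if not set(self.resources) <= ids:
            raise ValueError("resource profile for unknown participant")
        if not set(self.eq5d["id"]) <= ids:
            raise ValueError("EQ-5D response for unknown participant")
        if not set(self.eq5d["visit_day"]) <= set(VISIT_DAYS):
            raise ValueError("EQ-5D response at an unscheduled visit day")
        for pid, prof in self.resources.items():
            events = ([(p.start_day, p.end_day) for p in prof.prescriptions]
                      + list(prof.iv_segments) + list(prof.admissions))
            for s, e in events:
                if e > HORIZON:
                    raise ValueError(f"event beyond day {HORIZON} for {pid}")

    def utilities_wide(self) -> pd.DataFrame:
        """One row per participant: arm, age, sex, death_day and the
        tariff-scored utility at each visit (NaN where missing, 0 after death)."""
        base = self.participants.set_index("id")
        scored = self.eq5d.copy()
        scored["utility"] = [
            score_eq5d(tuple(levels))
            for levels in scored[EQ5D_COLUMNS].to_numpy()
        ]
        wide = scored.pivot(index="id", columns="visit_day", values="utility")
        wide = wide.reindex(columns=list(VISIT_DAYS)).reindex(base.index)
        wide.columns = [f"u_{d}" for d in wide.columns]
        out = pd.concat([base[["arm", "age", "sex", "death_day"]], wide], axis=1)
        for day in VISIT_DAYS:  # zero utility at visits after death
            died = out["death_day"].notna() & (out["death_day"] < day)
            out.loc[died, f"u_{day}"] = 0.0
        return out.reset_index()

    def to_csv(self, directory: str | Path) -> None:
        """Write the five input tables (participants, prescriptions,
        iv_segments, admissions + opat, eq5d) as CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / "participants.csv", index=False)
        rx, seg, adm, opat = [], [], [], []
        for pid, prof in sorted(self.resources.items()):
            for p in prof.prescriptions:
                rx.append((pid, p.drug, p.route, p.start_day, p.end_day))
            for s, e in prof.iv_segments:
                seg.append((pid, s, e))
            for s, e in prof.admissions:
                adm.append((pid, s, e))
            opat.append((pid, prof.opat_type))
        pd.DataFrame(rx, columns=["id", "drug", "route", "start_day", "end_day"]
                     ).to_csv(directory / "prescriptions.csv", index=False)
        pd.DataFrame(seg, columns=["id", "start_day", "end_day"]
                     ).to_csv(directory / "iv_segments.csv", index=False)
        pd.DataFrame(adm, columns=["id", "start_day", "end_day"]
                     ).to_csv(directory / "admissions.csv", index=False)
        pd.DataFrame(opat, columns=["id", "opat_type"]
                     ).to_csv(directory / "opat.csv", index=False)
        self.eq5d.to_csv(directory / "eq5d.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "TrialDataset":
        directory = Path(directory)
        participants = pd.read_csv(directory / "participants.csv")
        rx = pd.read_csv(directory / "prescriptions.csv")
        seg = pd.read_csv(directory / "iv_segments.csv")
        adm = pd.read_csv(directory / "admissions.csv")
        opat = pd.read_csv(directory / "opat.csv")
        eq5d = pd.read_csv(directory / "eq5d.csv")
        opat_map = dict(zip(opat["id"], opat["opat_type"]))
        resources: dict[str, ResourceProfile] = {}
        for pid in opat_map:
            p_rx = tuple(
                Prescription(r.drug, r.route, int(r.start_day), int(r.end_day))
                for r in rx[rx["id"] == pid].itertuples())
            p_seg = tuple((int(r.start_day), int(r.end_day))
                          for r in seg[seg["id"] == pid].itertuples())
            p_adm = tuple((int(r.start_day), int(r.end_day))
                          for r in adm[adm["id"] == pid].itertuples())
            resources[pid] = ResourceProfile(
                participant_id=pid, prescriptions=p_rx, iv_segments=p_seg,
                admissions=p_adm, opat_type=opat_map[pid])
        return cls(participants=participants, resources=resources, eq5d=eq5d)


# ---------------------------------------------------------------------------
# Utility generation on the tariff grid
# ---------------------------------------------------------------------------

_STATES = sorted(all_states_scored().items(), key=lambda kv: kv[1])
_SCORE_GRID = np.array([s for _, s in _STATES])
_GRID_LEVELS = [levels for levels, _ in _STATES]


def _censored_normal_mean(m: float, s: float, a: float, b: float) -> float:
    alpha, beta = (a - m) / s, (b - m) / s
    return (a * stats.norm.cdf(alpha) + b * stats.norm.sf(beta)
            + m * (stats.norm.cdf(beta) - stats.norm.cdf(alpha))
            + s * (stats.norm.pdf(alpha) - stats.norm.pdf(beta)))


def _adjusted_mean(target: float, s: float,
                   a: float = UTILITY_FLOOR, b: float = 1.0) -> float:
    """Latent mean whose [a, b]-censored normal mean equals ``target``."""
    if s <= 0:
        return target
    return optimize.brentq(
        lambda m: _censored_normal_mean(m, s, a, b) - target,
        a - 6 * s, b + 6 * s, xtol=1e-10)


def _round_to_grid(u: float, rng: np.random.Generator) -> tuple[int, ...]:
    """Stochastically round a target utility to an adjacent tariff score so the
    expected score equals ``u`` exactly; returns the EQ-5D levels."""
    j = int(np.searchsorted(_SCORE_GRID, u))
    if j <= 0:
        return _GRID_LEVELS[0]
    if j >= len(_SCORE_GRID):
        return _GRID_LEVELS[-1]
    lo, hi = _SCORE_GRID[j - 1], _SCORE_GRID[j]
    p_hi = 0.0 if hi == lo else (u - lo) / (hi - lo)
    return _GRID_LEVELS[j] if rng.random() < p_hi else _GRID_LEVELS[j - 1]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _gamma_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    shape = (mean / sd) ** 2
    return rng.gamma(shape, sd ** 2 / mean)


def _conditional_moments(p: float, mean: float, sd: float) -> tuple[float, float]:
    """Moments of the positive part of a zero-inflated variable with
    occurrence probability ``p`` and marginal (mean, sd)."""
    if p <= 0:
        return 0.0, 0.0
    mu_c = mean / p
    var_c = (sd ** 2 + mean ** 2) / p - mu_c ** 2
    if var_c <= 0:
        raise ConfigurationError(
            f"iv_any probability {p} too small for marginal moments "
            f"({mean}, {sd})")
    return mu_c, math.sqrt(var_c)


def _layered_segments(total_days: int, start: int,
                      window_end: int) -> list[tuple[int, int]]:
    """Lay ``total_days`` therapy-days into overlapping segments starting at
    ``start`` (simultaneous drugs stack as extra layers within the window)."""
    width = window_end - start + 1
    segments = []
    remaining = total_days
    while remaining > 0 and width > 0:
        seg = min(remaining, width)
        segments.append((start, start + seg - 1))
        remaining -= seg
    return segments


def _draw_iv_segments(rng, params: ArmResourceParams, period: str,
                      ) -> list[tuple[int, int]]:
    p = params.iv_any[period]
    if rng.random() >= p:
        return []
    mean, sd = params.iv_days[period]
    mu_c, sd_c = _conditional_moments(p, mean, sd)
    total = max(1, round(_gamma_draw(rng, mu_c, sd_c)))
    if period == "intervention":
        start = 1 if p >= 1.0 else int(rng.integers(1, 29))
        return _layered_segments(total, start, INTERVENTION_END)
    start = int(rng.integers(INTERVENTION_END + 1, 301))
    return _layered_segments(total, start, HORIZON)


def _draw_prescriptions(rng, params: ArmResourceParams, period: str,
                        ) -> list[Prescription]:
    window = ((1, INTERVENTION_END) if period == "intervention"
              else (INTERVENTION_END + 1, HORIZON))
    width = window[1] - window[0] + 1
    count = 1 + int(rng.poisson(max(params.n_rx[period] - 1, 0.0)))
    mean, sd = params.abx_days[period]
    total = max(1.0, _gamma_draw(rng, mean, sd))
    shares = rng.dirichlet(np.ones(count)) * total
    out = []
    for share in shares:
        dur = int(min(max(1, round(share)), width))
        start = int(rng.integers(window[0], window[1] - dur + 2))
        if rng.random() < params.iv_route_frac[period]:
            drug, route = "iv_agent", "iv"
        elif rng.random() < params.combo_frac[period]:
            drug, route = "oral_combination", "oral"
        else:
            drug, route = "oral_standard", "oral"
        out.append(Prescription(drug, route, start, start + dur - 1))
    return out


def _draw_admissions(rng, params: ArmResourceParams) -> list[tuple[int, int]]:
    # every participant is a post-surgical inpatient from day 1
    nights = max(1, round(_gamma_draw(rng, *params.first_los)))
    admissions = [(1, 1 + nights)]
    for _ in range(int(rng.poisson(params.post_admission_rate))):
        start = int(rng.integers(50, 341))
        nights = max(1, round(_gamma_draw(rng, *params.post_los_each)))
        admissions.append((start, min(start + nights, HORIZON)))
    return admissions


def _truncate_at_death(profile: ResourceProfile, day: int) -> ResourceProfile:
    rx = tuple(dc_replace(p, end_day=min(p.end_day, day))
               for p in profile.prescriptions if p.start_day <= day)
    seg = tuple((s, min(e, day)) for s, e in profile.iv_segments if s <= day)
    adm = tuple((s, min(e, day)) for s, e in profile.admissions if s <= day)
    return dc_replace(profile, prescriptions=rx, iv_segments=seg, admissions=adm)


def generate_trial(config: SynthConfig, with_missingness: bool = True,
                   ) -> TrialDataset:
    """Generate a complete synthetic trial, then (by default) impose the
    configured EQ-5D and resource-record missingness.

    Deterministic for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    adj_means = {arm: {d: _adjusted_mean(m, s)
                       for d, (m, s) in config.utility_anchors[arm].items()}
                 for arm in ARMS}
    opat_types = list(config.opat_mix)
    opat_probs = np.array([config.opat_mix[t] for t in opat_types])
    cat_labels = [c for c, _ in SURGICAL_CATEGORIES]
    cat_probs = np.array([p for _, p in SURGICAL_CATEGORIES])
    cat_probs = cat_probs / cat_probs.sum()
    rho = config.utility_rho

    part_rows, eq5d_rows = [], []
    resources: dict[str, ResourceProfile] = {}
    for arm in ARMS:
        params = config.arm_effects[arm]
        for i in range(config.n_per_arm):
            pid = f"{arm}_{i + 1:04d}"
            age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                              *config.age_range))
            sex = int(rng.random() < config.male_prob)  # 1 = male
            death_day = (int(rng.integers(1, HORIZON + 1))
                         if rng.random() < config.death_prob else None)
            category = cat_labels[int(rng.choice(len(cat_labels), p=cat_probs))]

            profile = ResourceProfile(
                participant_id=pid,
                prescriptions=tuple(
                    _draw_prescriptions(rng, params, "intervention")
                    + _draw_prescriptions(rng, params, "post")),
                iv_segments=tuple(
                    _draw_iv_segments(rng, params, "intervention")
                    + _draw_iv_segments(rng, params, "post")),
                admissions=tuple(_draw_admissions(rng, params)),
                opat_type=opat_types[int(rng.choice(len(opat_types),
                                                    p=opat_probs))],
            )
            if death_day is not None:
                profile = _truncate_at_death(profile, death_day)
            resources[pid] = profile

            z = rng.normal()
            for day in VISIT_DAYS:
                if day != VISIT_DAYS[0]:
                    z = rho * z + math.sqrt(1 - rho ** 2) * rng.normal()
                if death_day is not None and day > death_day:
                    continue  # the dead return no questionnaires
                m, s = config.utility_anchors[arm][day]
                target = float(np.clip(adj_means[arm][day] + s * z,
                                       UTILITY_FLOOR, 1.0))
                levels = _round_to_grid(target, rng)
                eq5d_rows.append((pid, day) + levels)

            part_rows.append((pid, arm, age, sex, category, death_day))

    participants = pd.DataFrame(
        part_rows, columns=["id", "arm", "age", "sex", "surgical_category",
                            "death_day"])
    participants["death_day"] = participants["death_day"].astype("Int64")
    eq5d = pd.DataFrame(eq5d_rows, columns=["id", "visit_day"] + EQ5D_COLUMNS)
    data = TrialDataset(participants=participants, resources=resources,
                        eq5d=eq5d)
    if with_missingness:
        data = impose_missingness(data, config,
                                  rng=np.random.default_rng(config.seed + 1))
    return data


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def _logistic_normal_offset(target: float, sigma: float) -> float:
    """Intercept ``c`` with ``E[invlogit(c + sigma·Z)] = target``, Z ~ N(0,1)
    (Gauss–Hermite quadrature), so the participant-level missingness
    propensity does not distort the per-visit marginal rate."""
    from scipy.special import expit

    if sigma <= 0:
        return math.log(target / (1 - target))

    def marginal(c: float) -> float:
        return float((_GH_WEIGHTS * expit(
            c + sigma * math.sqrt(2.0) * _GH_NODES)).sum() / math.sqrt(math.pi))

    return optimize.brentq(lambda c: marginal(c) - target, -40.0, 40.0,
                           xtol=1e-10)


def impose_missingness(data: TrialDataset, config: SynthConfig,
                       rng: np.random.Generator | None = None) -> TrialDataset:
    """Delete EQ-5D cells under a missing-at-random mechanism and whole
    resource records completely at random.

    The deletion logit for the response at visit ``v`` is a marginal-corrected
    visit offset (hitting ``missing_prob[v]`` on average) plus a per-participant
    normal propensity (SD ``propensity_sd`` — this correlates missingness
    across a participant's visits, reproducing the trial's much-lower joint
    completeness), plus observed-covariate terms:
    ``c_arm (iv − ½) + c_age (age − 60)/10 + c_prior (u_prev − ½)`` with
    ``u_prev`` the last *surviving* earlier utility.  The propensity is drawn
    independently of outcomes, so the mechanism stays ignorable given the
    observed data and imputation recovery is testable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    coefs = config.mar_coefficients
    sigma = coefs.get("propensity_sd", 0.0)
    offsets = {day: _logistic_normal_offset(p, sigma)
               for day, p in config.missing_prob.items() if 0.0 < p < 1.0}
    scored = data.eq5d.copy()
    scored["utility"] = [score_eq5d(tuple(lv))
                         for lv in scored[EQ5D_COLUMNS].to_numpy()]
    cell = {(r.id, r.visit_day): (k, r.utility)
            for k, r in enumerate(scored.itertuples())}
    info = data.participants.set_index("id")

    # visits are processed in order and the prior-utility driver uses only the
    # last *surviving* response, so deletion depends on observed data alone
    keep = np.ones(len(data.eq5d), dtype=bool)
    for pid in data.participants["id"]:
        lp_fixed = (coefs.get("arm", 0.0) * ((info.at[pid, "arm"] == "iv") - 0.5)
                    + coefs.get("age_per_decade", 0.0)
                    * (info.at[pid, "age"] - 60.0) / 10.0
                    + sigma * rng.normal())
        last_observed = None
        for day in VISIT_DAYS:
            if (pid, day) not in cell:
                continue
            k, utility = cell[(pid, day)]
            base = config.missing_prob.get(day, 0.0)
            if base <= 0.0:
                last_observed = utility
                continue
            if base >= 1.0:
                keep[k] = False
                continue
            lp = offsets[day] + lp_fixed
            if last_observed is not None:
                lp += coefs.get("prior_utility", 0.0) * (last_observed - 0.5)
            if rng.random() < 1.0 / (1.0 + math.exp(-lp)):
                keep[k] = False
            else:
                last_observed = utility

    resources = {pid: prof for pid, prof in data.resources.items()
                 if rng.random() >= config.resource_missing_prob}
    return TrialDataset(participants=data.participants.copy(),
                        resources=resources,
                        eq5d=data.eq5d.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Summary-calibrated trial (costs and QALYs drawn directly at published moments)
# ---------------------------------------------------------------------------

def summary_trial(n_per_arm: int = reference.N_PER_ARM, seed: int = 0,
                  cost_means: Mapping[str, float] | None = None,
                  cost_sds: Mapping[str, float] | None = None,
                  qaly_means: Mapping[str, float] | None = None,
                  qaly_sds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Participant-level (arm, total_cost, total_qaly) drawn directly from the
    published arm-level moments: gamma total costs (strictly positive, skewed)
    at the base-case means with complete-case SDs, and normal QALYs.

    This bypasses resource-level structure entirely; it is the vehicle for
    checking that the incremental-analysis estimators recover known arm
    differences at the trial's sample size.
    """
    cost_means = cost_means or reference.BASE_CASE["cost_mean"]
    cost_sds = cost_sds or {a: sd for a, (_, sd)
                            in reference.TOTAL_COST_COMPLETE_CASE.items()}
    qaly_means = qaly_means or reference.BASE_CASE["qaly_mean"]
    qaly_sds = qaly_sds or {a: sd for a, (_, sd)
                            in reference.TOTAL_QALY_COMPLETE_CASE.items()}
    rng = np.random.default_rng(seed)
    frames = []
    for arm in ARMS:
        m, s = cost_means[arm], cost_sds[arm]
        shape = (m / s) ** 2
        costs = rng.gamma(shape, s ** 2 / m, size=n_per_arm)
        qalys = rng.normal(qaly_means[arm], qaly_sds[arm], size=n_per_arm)
        frames.append(pd.DataFrame({
            "id": [f"{arm}_{i + 1:04d}" for i in range(n_per_arm)],
            "arm": arm, "total_cost": costs, "total_qaly": qalys}))
    return pd.concat(frames, ignore_index=True)
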