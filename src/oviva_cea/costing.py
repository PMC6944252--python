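"""Costing of trial resource use: antibiotics, inpatient stays, IV administration.

Turns a participant's :class:`ResourceProfile` into a :class:`CostBreakdown`
with costs split by category (antibiotics / inpatient / IV administration) and
period (intervention, days 1–42 / post-intervention, days 43–365).

Day conventions
---------------
Day 1 is the first day of randomised treatment.  All intervals are closed
``[start_day, end_day]`` in whole days.  Inpatient bed-days are counted as
*nights* (``end − start``), priced per overnight stay; the night spent between
day ``d`` and ``d+1`` is indexed by its morning ``d+1``, so a night belongs to
the intervention period iff it ends on or before day 42.  Events are truncated
at day 365.

IV line episodes
----------------
IV therapy segments (line-in-use intervals; simultaneous IV drugs may overlap)
are merged into *episodes*: a gap of two whole days or less between segments
does not require a new line, a gap of three or more does.  Each episode is
charged one line insertion plus one removal.  The initial episode's line cost
is always assigned to the intervention period; later episodes are assigned to
the period containing their start day.

OPAT
----
The OPAT (outpatient parenteral antimicrobial therapy) team cost is applied at
one hour per calendar day of IV therapy, at the rate of the participant's OPAT
type recorded at day 42.  District-nurse days inside an inpatient admission
accrue no OPAT cost (administration is covered by the bed-day).  'Inpatient'
(hospital infusion centre) type is charged £109/h while admitted and the
weighted fallback rate after discharge.  Missing OPAT type uses the weighted
fallback everywhere out of admission: 3/5 district nurse + 2/5
self-administration = £34.80/h by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import reference

HORIZON_DAYS = 365
INTERVENTION_END_DAY = 42

OPAT_TYPES = ("district_nurse", "inpatient", "self_administer", "missing")
CATEGORIES = ("antibiotics", "inpatient", "iv_admin")
PERIODS = ("intervention", "post")

#: Fallback policies for where the trial applied the weighted-average OPAT rate
#: (missing OPAT type; 'inpatient' type after discharge).
OPAT_FALLBACKS = ("weighted", "district_nurse", "self_administer")


class PricingError(KeyError):
    """An antibiotic appears in a prescription but not in the price list."""


@dataclass(frozen=True)
class Prescription:
    drug: str
    route: str  # "iv" or "oral"
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.route not in ("iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        _check_interval(self.start_day, self.end_day)

    @property
    def duration(self) -> int:
        return self.end_day - self.start_day + 1


def _check_interval(start: int, end: int) -> None:
    if start < 1 or end < start:
        raise ValueError(f"invalid interval ({start}, {end}): need 1 <= start <= end")


@dataclass(frozen=True)
class ResourceProfile:
    """One participant's resource use over follow-up."""

    participant_id: str
    prescriptions: tuple[Prescription, ...] = ()
    iv_segments: tuple[tuple[int, int], ...] = ()
    admissions: tuple[tuple[int, int], ...] = ()
    opat_type: str = "missing"

    def __post_init__(self):
        if self.opat_type not in OPAT_TYPES:
            raise ValueError(
                f"unknown OPAT type {self.opat_type!r}; expected one of {OPAT_TYPES}")
        for s, e in self.iv_segments:
            _check_interval(s, e)
        for s, e in self.admissions:
            if s < 1 or e < s:  # zero-night stays (s == e) are allowed
                raise ValueError(f"invalid admission ({s}, {e})")


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs in GBP; defaults are the trial's 2015 values."""

    picc_insertion: float = reference.UNIT_COSTS["picc_insertion"]
    line_removal: float = reference.UNIT_COSTS["line_removal"]
    bed_day: float = reference.UNIT_COSTS["bed_day"]
    opat_district_nurse: float = reference.UNIT_COSTS["opat_district_nurse"]
    opat_inpatient_centre: float = reference.UNIT_COSTS["opat_inpatient_centre"]
    opat_self_administer: float = reference.UNIT_COSTS["opat_self_administer"]
    antibiotic_daily_cost: Mapping[str, float] = field(default_factory=dict)
    inflation_multiplier: float = 1.0

    def __post_init__(self):
        for name in ("picc_insertion", "line_removal", "bed_day",
                     "opat_district_nurse", "opat_inpatient_centre",
                     "opat_self_administer"):
            if getattr(self, name) < 0:
                raise ValueError(f"unit cost {name} must be >= 0")
        if any(v < 0 for v in self.antibiotic_daily_cost.values()):
            raise ValueError("antibiotic daily costs must be >= 0")
        if self.inflation_multiplier < 0:
            raise ValueError("inflation_multiplier must be >= 0")

    @property
    def line_event(self) -> float:
        """Cost of one IV line episode: insertion plus removal."""
        return self.picc_insertion + self.line_removal

    @property
    def opat_weighted(self) -> float:
        """Weighted fallback OPAT rate: 3/5 district nurse + 2/5 self."""
        return (reference.OPAT_WEIGHT_DISTRICT_NURSE * self.opat_district_nurse
                + reference.OPAT_WEIGHT_SELF * self.opat_self_administer)

    def daily_cost(self, drug: str) -> float:
        try:
            return self.antibiotic_daily_cost[drug]
        except KeyError:
            raise PricingError(f"no daily cost for drug {drug!r}") from None

    @classmethod
    def from_csv(cls, unit_cost_path: str | Path,
                 drug_price_path: str | Path | None = None,
                 inflation_multiplier: float = 1.0) -> "UnitCostTable":
        """Read unit costs from a two-column ``item,gbp`` file and, optionally,
        antibiotic prices from a ``drug,gbp_per_day`` file."""
        fields = {}
        with open(unit_cost_path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("item", ""):
                    continue
                fields[row[0].strip()] = float(row[1])
        drugs: dict[str, float] = {}
        if drug_price_path is not None:
            with open(drug_price_path, newline="") as fh:
                for row in csv.reader(fh):
                    if not row or row[0].strip().lower() in ("drug", ""):
                        continue
                    drugs[row[0].strip()] = float(row[1])
        return cls(antibiotic_daily_cost=drugs,
                   inflation_multiplier=inflation_multiplier, **fields)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-participant GBP costs by category × period.

    Totals are derived sums, so conservation (grand total = Σ categories =
    Σ periods) holds exactly by construction.
    """

    antibiotics_intervention: float = 0.0
    antibiotics_post: float = 0.0
    inpatient_intervention: float = 0.0
    inpatient_post: float = 0.0
    iv_admin_intervention: float = 0.0
    iv_admin_post: float = 0.0

    def component(self, category: str, period: str) -> float:
        return getattr(self, f"{category}_{period}")

    def category_total(self, category: str) -> float:
        return sum(self.component(category, p) for p in PERIODS)

    def period_total(self, period: str) -> float:
        return sum(self.component(c, period) for c in CATEGORIES)

    @property
    def grand_total(self) -> float:
        return sum(self.component(c, p) for c in CATEGORIES for p in PERIODS)

    def as_dict(self) -> dict[str, float]:
        d = {f"{c}_{p}": self.component(c, p) for c in CATEGORIES for p in PERIODS}
        d.update({f"{c}_total": self.category_total(c) for c in CATEGORIES})
        d.update({f"total_{p}": self.period_total(p) for p in PERIODS})
        d["total_cost"] = self.grand_total
        return d


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def truncate_profile(profile: ResourceProfile,
                     horizon: int = HORIZON_DAYS) -> ResourceProfile:
    """Clip every event at the follow-up horizon; drop events starting after it."""

    def _clip(intervals: Iterable[tuple[int, int]]):
        return tuple((s, min(e, horizon)) for s, e in intervals if s <= horizon)

    rx = tuple(replace(p, end_day=min(p.end_day, horizon))
               for p in profile.prescriptions if p.start_day <= horizon)
    return replace(profile, prescriptions=rx,
                   iv_segments=_clip(profile.iv_segments),
                   admissions=_clip(profile.admissions))


def merge_iv_episodes(segments: Sequence[tuple[int, int]],
                      max_gap: int = 2) -> list[tuple[int, int]]:
    """Merge IV therapy segments into line episodes.

    The gap between consecutive segments is the number of whole days strictly
    between them (``next.start − prev.end − 1``); a gap of ``max_gap`` days or
    less keeps the same line.  Overlapping segments (simultaneous IV drugs)
    always merge.  Idempotent and invariant to input order.
    """
    if not segments:
        return []
    ordered = sorted(segments)
    episodes = [list(ordered[0])]
    for s, e in ordered[1:]:
        gap = s - episodes[-1][1] - 1
        if gap <= max_gap:
            episodes[-1][1] = max(episodes[-1][1], e)
        else:
            episodes.append([s, e])
    return [tuple(ep) for ep in episodes]


def line_event_cost(episodes: Sequence[tuple[int, int]],
                    costs: UnitCostTable) -> float:
    """One insertion + one removal per IV line episode."""
    return len(episodes) * costs.line_event


def opat_daily_rate(opat_type: str, in_admission: bool, costs: UnitCostTable,
                    missing_fallback: str = "weighted") -> float:
    """GBP for one hour of OPAT on one IV-therapy day.

    ``missing_fallback`` replaces the weighted-average rate wherever it would
    apply (missing OPAT type; 'inpatient' type after discharge) — this is the
    knob the two OPAT sensitivity scenarios turn.
    """
    if opat_type not in OPAT_TYPES:
        raise ValueError(
            f"unknown OPAT type {opat_type!r}; expected one of {OPAT_TYPES}")
    if missing_fallback not in OPAT_FALLBACKS:
        raise ValueError(f"unknown OPAT fallback {missing_fallback!r}")

    def fallback(in_adm: bool) -> float:
        if missing_fallback == "district_nurse":
            return 0.0 if in_adm else costs.opat_district_nurse
        if missing_fallback == "self_administer":
            return costs.opat_self_administer
        # weighted mixture inherits each component's admission behaviour:
        # the district-nurse share is suppressed during admissions.
        if in_adm:
            return reference.OPAT_WEIGHT_SELF * costs.opat_self_administer
        return costs.opat_weighted

    if opat_type == "district_nurse":
        return 0.0 if in_admission else costs.opat_district_nurse
    if opat_type == "self_administer":
        return costs.opat_self_administer
    if opat_type == "inpatient":
        return costs.opat_inpatient_centre if in_admission else fallback(False)
    return fallback(in_admission)  # missing


def _admission_days(admissions: Sequence[tuple[int, int]]) -> set[int]:
    """Calendar days on which the participant is in hospital (inclusive)."""
    days: set[int] = set()
    for s, e in admissions:
        days.update(range(s, e + 1))
    return days


def cost_iv_administration(profile: ResourceProfile, costs: UnitCostTable,
                           missing_fallback: str = "weighted") -> dict[str, float]:
    """Line insertion/removal per episode plus per-day OPAT, split by period."""
    out = {"intervention": 0.0, "post": 0.0}
    episodes = merge_iv_episodes(profile.iv_segments)
    for i, (s, _e) in enumerate(episodes):
        if i == 0 or s <= INTERVENTION_END_DAY:
            out["intervention"] += costs.line_event
        else:
            out["post"] += costs.line_event
    in_hospital = _admission_days(profile.admissions)
    iv_days: set[int] = set()
    for s, e in profile.iv_segments:
        iv_days.update(range(s, e + 1))
    for day in iv_days:
        rate = opat_daily_rate(profile.opat_type, day in in_hospital, costs,
                               missing_fallback)
        period = "intervention" if day <= INTERVENTION_END_DAY else "post"
        out[period] += rate
    return out


def cost_antibiotics(profile: ResourceProfile,
                     costs: UnitCostTable) -> dict[str, float]:
    """Daily drug cost × duration; simultaneous courses are additive.

    A course spanning day 42 is split at the boundary: its days up to and
    including day 42 are intervention-period cost, the remainder post.
    """
    out = {"intervention": 0.0, "post": 0.0}
    for p in profile.prescriptions:
        daily = costs.daily_cost(p.drug)
        pre_days = max(0, min(p.end_day, INTERVENTION_END_DAY) - p.start_day + 1)
        out["intervention"] += daily * pre_days
        out["post"] += daily * (p.duration - pre_days)
    return out


def cost_inpatient(profile: ResourceProfile,
                   costs: UnitCostTable) -> dict[str, float]:
    """Bed-days (nights, ``end − start``) × cost per overnight stay.

    A night belongs to the intervention period iff its morning is on or before
    day 42, so a stay (40, 45) contributes 2 intervention + 3 post nights.
    """
    out = {"intervention": 0.0, "post": 0.0}
    for s, e in profile.admissions:
        nights_pre = max(0, min(e, INTERVENTION_END_DAY) - s)
        out["intervention"] += costs.bed_day * nights_pre
        out["post"] += costs.bed_day * ((e - s) - nights_pre)
    return out


def total_cost(profile: ResourceProfile, costs: UnitCostTable,
               missing_fallback: str = "weighted") -> CostBreakdown:
    """Assemble the full per-participant cost breakdown.

    The profile is truncated at 365 days first; the inflation multiplier is
    applied uniformly to every component.
    """
    profile = truncate_profile(profile)
    abx = cost_antibiotics(profile, costs)
    inp = cost_inpatient(profile, costs)
    iva = cost_iv_administration(profile, costs, missing_fallback)
    k = costs.inflation_multiplier
    return CostBreakdown(
        antibiotics_intervention=k * abx["intervention"],
        antibiotics_post=k * abx["post"],
        inpatient_intervention=k * inp["intervention"],
        inpatient_post=k * inp["post"],
        iv_admin_intervention=k * iva["intervention"],
        iv_admin_post=k * iva["post"],
    )
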