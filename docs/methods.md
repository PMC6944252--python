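# Methods

This package re-implements, as a tested pipeline, the within-trial cost-utility
analysis of the OVIVA randomised trial (oral versus intravenous antibiotics for
the first six weeks of treatment of bone and joint infection; 527 participants
per arm, 12-month horizon, NHS and personal social services perspective, 2015
GBP, no discounting).  Participant-level trial data are not publicly deposited,
so a synthetic-trial generator calibrated to the published arm-level summaries
stands in for them; everything downstream of the generator operates on ordinary
participant-level tables and works identically on real data in the same format.

## Costing model

Each participant's resource use is costed in three categories, split at the
day-42 boundary between the intervention period (days 1–42 of randomised
therapy) and the post-intervention period (days 43–365).

**Antibiotics.** Cost = daily drug cost × days prescribed, summed over
prescriptions; simultaneous courses are additive.  A course spanning day 42 is
split at the boundary.  Unit prices come from a per-drug GBP/day table
(editable CSV; a formulary lookup is the user's responsibility for real data).

**Inpatient stays.** Bed-days are nights (`end − start`), priced at £296 per
overnight stay.  The night spent between days *d* and *d + 1* is indexed by its
morning, so a stay (40, 45) contributes 2 intervention and 3 post nights, and a
same-day admission costs nothing.

**IV administration.** IV therapy segments (line-in-use intervals; simultaneous
IV drugs overlap) are merged into line *episodes*: a gap of two whole days or
less between segments keeps the same line, three or more forces a new line.
Each episode is charged one PICC insertion (£190) plus one removal (£34).  The
initial episode's line cost is always assigned to the intervention period;
later episodes go to the period containing their start.  On every calendar day
of IV therapy one hour of OPAT time is charged at the rate of the OPAT type
recorded at day 42: district nurse £58/h, hospital infusion centre £109/h,
self-administration £0/h, and a weighted fallback of 3/5 district nurse + 2/5
self-administration (£34.80/h) for participants with a missing OPAT type — the
witnessed ratio of the two types in the trial.

Three costing choices were genuinely open and are resolved as follows:

- *Self-administration is priced at £0/h.*  The published unit-cost table
  prices only staffed OPAT time; self-administration consumes none, and
  consumables are folded into the line-insertion kit.
- *District-nurse OPAT is not charged on IV days inside an inpatient
  admission* (administration is covered by the bed-day); the infusion-centre
  type is charged £109/h while admitted and the weighted fallback after
  discharge.  Whether the trial did the same is not stated.
- *The weighted fallback inherits its components' admission behaviour*, so a
  missing-type participant accrues £34.80/h out of admission and 2/5 × £0 = £0
  in admission.

A consequence worth knowing: cost is **not** globally monotone in resource
events.  An added IV segment can bridge two episodes into one (removing a £224
line event), and an added admission can suppress district-nurse OPAT days.
Both are deliberate consequences of the rules above.

Inflation adjustment is exposed as a single multiplier (default 1.0 = 2015
GBP); no index series is shipped.

## Utilities and QALYs

EQ-5D-3L responses are valued with the UK time-trade-off tariff (MVH study):
1 − 0.081·[any dimension > 1] − per-dimension decrements − 0.269·[any
dimension at level 3]; full health scores exactly 1 and the worst state
−0.594.  The coefficient table is pluggable, so other three-level value sets
can be supplied, but none are bundled.

QALYs are the area under the piecewise-linear utility curve over visits at
days 0, 14, 42, 120 and 365, each interval contributing
(u₁ + u₂)/2 × (d₂ − d₁)/365 years.  Participants who die score zero utility
thereafter.  Two death conventions are implemented: the default interpolates
linearly from the last pre-death visit to zero at the death day; the
alternative (`death_interpolation="next_visit"`) zeroes only from the next
scheduled visit.  Which one the trial used is not stated; the default is the
slightly more favourable and more common convention.

The incremental QALY model is gaussian with identity link, adjusting for
baseline utility and age.  Constant covariates are dropped automatically so
the arm coefficient stays identified on degenerate designs.

## Missing data

Missing total costs are imputed at the aggregate per-participant level and
missing utilities per visit, by chained equations with predictive mean
matching (5 donors), m = 20 imputations and 10 sweeps by default.  The engine
is `statsmodels`' MICE implementation run under explicit derived seeds, one
independent chain per imputation.  Default predictors are arm, age, sex and
the other (possibly imputed) outcome columns; the trial names its clinical
companion's covariate list, which is unpublished, so the default is declared
rather than inferred and is configurable.  Estimates are pooled with Rubin's
rules, with the (m − 1)(1 + W̄/((1 + 1/m)B))² degrees of freedom for the t
reference and a normal reference when B = 0.  Mean imputation (within arm)
and complete-case analysis are available as sensitivity routes; with no
missing data all three coincide exactly.

## Incremental analysis and uncertainty

Incremental cost is the arm coefficient of a gamma-family identity-link GLM of
total cost on arm; on a two-group design this equals the arithmetic difference
of arm means (the gamma variance function only reweights within-group, which
cancels for a saturated design) — a property used as a test oracle.  Costs
must be strictly positive; this is guaranteed structurally because every
participant has an admission from day 1.

Tabulated differences are IV − oral, matching the published tables.  The
bootstrap cloud, CE plane and CEAC are oriented oral − IV, matching the
published figure.  Uncertainty uses 1,000 nonparametric bootstrap resamples of
the unadjusted, non-imputed complete cases, stratified within arm (the trial
does not say whether its resampling was stratified; stratification preserves
the arm sizes).  The 95% ellipse is the chi-square(2 df) contour of a
bivariate normal fitted to the cloud's mean and covariance (a convex-hull
alternative was considered and dropped: the normal contour is standard
practice and testable against its own coverage).  The CEAC reports, per
willingness-to-pay λ, the fraction of resamples with positive oral net
monetary benefit λ·ΔQALY − Δcost; at λ = 0 it equals the probability of cost
saving and tends to the probability of a QALY gain as λ → ∞.

Sensitivity scenarios: complete case, within-arm mean imputation, and the two
OPAT fallback variants (all-district-nurse, all-self-administration, applied
wherever the weighted rate would be).  The trial analysed scenarios with
two-sample t-tests; here the per-imputation Welch difference is Rubin-pooled
for the MI-based scenarios (a single t-test is undefined across m datasets),
while the base case uses the GLM.

## The synthetic-data generator

The generator emulates the trial's published structure; its defaults are the
calibration, not free dials:

- **Demographics**: age ~ normal(59.5, 14.5) clipped to 18–92 (published
  median 61, IQR 49–70, range 18–92); 64.3% male; eight baseline surgical
  categories at the published frequencies.
- **Resource durations** are gamma draws with shape/scale solved from the
  published per-arm mean/SD for each measure and period (costs "are likely to
  be skewed").  IV therapy in the oral arm is zero-inflated (occurrence
  probabilities 0.30/0.18 for intervention/post, conditional moments solved
  from the published marginals).  IV therapy days sum simultaneous drugs:
  totals beyond the window width stack as overlapping segments, so summed
  durations match the published means while calendar line-days (which drive
  OPAT cost) are shorter.  Everyone is an inpatient from day 1.
- **Antibiotic prices**: three synthetic agents (IV £24.90/day, combination
  oral £18.00/day, standard oral £4.50/day) with per-arm/period route mixes
  solved once from the published blended cost-per-antibiotic-day ratios
  (published antibiotic cost ÷ published antibiotic days per arm and period).
- **Utilities**: a latent standard-normal AR(1) across visits (ρ = 0.6; no
  longitudinal correlation is published — chosen so baseline adjustment has
  something to adjust) is mapped to a target utility with the published
  per-visit mean/SD, mean-corrected for censoring at the tariff range, then
  stochastically rounded to the two adjacent scores of the 243-state tariff
  grid.  Expected scored utility therefore equals the anchor exactly; the SD
  is slightly shrunk by censoring.
- **Deaths**: probability 23/1054, day uniform on follow-up (only the count
  is published); deaths truncate all events and questionnaires.
- **Missingness**: EQ-5D cells are deleted with probability
  invlogit(offset_v + σ·b_i + 0.2(iv − ½) + 0.15(age − 60)/10 − 0.8(u_prev − ½)),
  where b_i is a per-participant standard-normal propensity with σ = 2.5 and
  offset_v is solved (Gauss–Hermite quadrature) so the marginal per-visit rate
  equals the published one (26.6% at baseline to 45.7% at one year).  The
  propensity correlates missingness within participant, reproducing the
  trial's ~34% joint completeness, which independent per-visit deletion would
  put near 10%; it is drawn independently of outcomes, so the mechanism stays
  ignorable.  The prior-utility driver uses only the last *surviving* earlier
  response, keeping the mechanism genuinely missing-at-random.  Resource
  records are deleted whole-participant completely at random (26/1054).
- **OPAT mix**: 42% district nurse, 20% infusion centre, 28% self-administer,
  10% missing — the district-nurse:self ratio is the published 3:2; the full
  four-way split is not published and was fixed once.

**What the generator does not emulate.**  Recruitment over calendar time,
sites, the randomisation algorithm, visit-window deviations, and any
participant-level correlation between resource use and utilities (they are
drawn independently given arm; in reality sicker patients cost more and score
lower).  Prescription route-days and IV line segments are drawn from their own
marginals rather than jointly.  Passing tests therefore demonstrate that the
*estimators* behave correctly under the trial's marginal structure, not that
they would be unbiased under every real-data correlation pattern.

**Calibration closure.**  Driving the resource anchors through the costing
rules reproduces the published inpatient cost almost exactly (bed-days × unit
cost) and antibiotic costs closely, but the IV-administration category is
structurally below its published value: with district-nurse OPAT suppressed
during admissions and OPAT paid per calendar line-day (not per summed
drug-day), no plausible OPAT mix reaches the published £3,527 IV-arm mean
(an all-infusion-centre mix caps near £3,000).  The synthetic IV-arm total
cost therefore sits roughly 15% below the published £13,275, and the closure
test asserts agreement within 20% — a tolerance fixed from this analysis, not
fitted.  Quantities that must match published effect sizes exactly (the
incremental-cost recovery checks) use the summary-calibrated generator
instead, which draws gamma total costs directly at the published base-case arm
means with complete-case SDs.

## Numerical choices and problem sizes

IRLS for the gamma GLM runs to relative tolerance 1e-8 (error on
non-convergence); Wald intervals use t critical values throughout (the trial
does not name its CI method).  Money is kept at full precision internally and
rounded only for presentation; QALYs are reported to 3 d.p.  Monetary
conservation (grand total = Σ categories = Σ periods) is exact by
construction, not by rounding.

Simulation-based tests run at sizes chosen to keep the whole suite fast while
leaving Monte-Carlo error well inside the asserted bounds: generator
calibration at 5,000 per arm, structural sweeps at 50 seeds × 10 per arm,
estimator-recovery checks at the trial's 527 per arm, MI recovery/coverage at
200 replicates of 100 per arm with m = 5, and the null-calibration checks at
100 seeds or 1,000 permutations.  All randomness flows through explicit seeds;
the pipeline writes a manifest (seed, config hash, package version) sufficient
to reproduce any results file byte-for-byte.

## Known limitations

The OPAT-in-admission convention and the £0 self-administration rate are
assumptions (see above); the imputation covariate list is declared, not the
trial's; the generator draws costs and utilities independently given arm; no
MNAR sensitivity models, no EQ-5D-5L or non-UK tariffs, no Hickman-line
pricing, no surgery costs (a pre-randomisation procedure), and no discounting
(horizon ≤ 1 year).
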