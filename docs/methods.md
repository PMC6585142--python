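# Methods

This note documents the models and procedures implemented in `neocds`, the
choices made where the underlying guideline or study report left the design
open, and what the synthetic-data checks do and do not demonstrate.

## Case model and derived measures

A case is one newborn at one assessment encounter. Every clinical
observation that can be *skipped* is tri-state (`yes` / `no` / `na`), so a
paper form's blank checkbox is representable and never silently reads as a
negative finding. Derived measures are computed, never entered:

- **Postnatal age** is the floor of elapsed time in whole days (a 6.9-day
  interval is age 6). The clinical "age in days" convention is a floor;
  eligibility is age < 28 days, strict.
- **Gestational age** is (days from LMP to birth)/7, kept unrounded
  internally and rendered to one decimal; preterm is < 37.0 weeks, strict,
  so a 259-day (37.0-week) gestation is term. Rounding before the preterm
  comparison could flip 36.96 weeks to term, so comparisons always use the
  exact ratio. Gestational age exists only when an LMP date does.
- **Weight change** is `100·(current − birth)/birth`, negative for loss.
- **Temperature** is normalised to Celsius ((F−32)·5/9) and rounded to
  0.1 °C before any threshold comparison; thresholds are defined in °C.

Validation collects structured issues (field, rule, message) rather than
raising on first error: weights must lie in (200, 8000] g, normalised
temperature in [25, 45] °C, the breath count in [0, 200], and datetimes must
be ordered (LMP ≤ birth ≤ assessment).

## Classification

Each of the 18 conditions maps to exactly one of positive / negative /
not-assessable. Missing inputs propagate not-assessable; composites
(small, very-low-weight, the two feeding composites) are positive as soon as
any available criterion fires, negative only when every criterion resolved
negative, and not-assessable only when nothing was available. This
asymmetry is deliberate: one adverse observation is evidence, but an
all-clear requires the full checklist.

Threshold choices that needed a decision:

- **Weight-loss bands.** The printed band edges overlap ("8–10 %" moderate
  and "> 10 %" severe). Bands are closed and severity strict, so a loss of
  exactly 10 % (small) or 15 % (non-small) is moderate. This keeps the three
  categories exclusive and exhaustive and matches the printed strict ">".
- **Unknown size.** When size is not assessable but both weights are
  present, weight loss is graded with the *non-small* bands (configurable via
  `unknown_size_uses_small_bands`). Without a size call there is no basis
  for the stricter small-infant bands; the choice is conservative against
  over-referral and is recorded here rather than buried in code.
- **Vital-sign thresholds are strict** (> 38.0 °C, < 35.5 °C, > 60 bpm):
  boundary values are negative.
- **The danger-sign set** driving `any_danger_sign` (and hence referral) is
  configurable; the default comprises the eight observed signs plus fever,
  hypothermia, fast breathing, severe weight loss, very low weight and
  feeding intolerance — i.e. everything that independently warrants
  facility care. Size status and moderate findings counsel rather than
  refer on their own.

Every threshold lives in `ClassificationConfig`; the classifier is
deterministic and total, and is cross-checked condition-for-condition
against an independently coded brute-force threshold checker on 10 000
random cases (boundary-heavy, with missingness) in the test suite.

## Management

Referral is the single-danger-sign rule — any positive condition in the
referral table refers — plus two small-infant conjunctions with lower
thresholds: small ∧ moderate-weight-loss and small ∧ breastfeeding-problems.
The guideline source names the counseling items but never prints the full
condition → advice mapping or the follow-up offsets, so these are explicit
package defaults in `ManagementConfig` (override from YAML, no code
change): small ∨ hypothermia → {KMC, thermal care}; small ∧
breastfeeding-problems → {small-infant breastfeeding advice, cup feeding};
any weight loss ∨ poor feeding → {increase feeding frequency};
breastfeeding-problems → {general breastfeeding support}; infected
umbilicus → {cord care}. Follow-up is +2 days for small or moderately
unwell infants, +7 days otherwise, and absent entirely when referred
(referral supersedes scheduling). Referral urgency tiers are not modelled;
refer is binary.

## Form engine and completeness

The engine is schema-generic: ordered items with range constraints,
soft ("check your entry") plausibility ranges that warn without blocking,
required double entry, computed fields, and skip predicates over earlier
answers only (enforced at schema construction, which also guarantees
termination: each step answers or skips one more item). Mobile-style
records are *produced through* the engine and therefore audit as fully
complete by construction — this structural asymmetry, not any parameter, is
what the completeness comparison measures. Paper-style records are ingested
as-is.

A full assessment requires every condition item resolved yes/no, a weight
(birth or current), a temperature, a respiratory rate, and at least one
recommendation. The gestational-age flag is defined only for records with
an LMP on file; records without one drop out of that denominator.

## Evaluation statistics

- Correctness of a call against gold: resolved and equal. A not-assessable
  call is incorrect by definition (a missed assessment cannot be correct);
  conditions the gold assessor could not resolve are excluded.
- Proportions compare on the 2×2 with Pearson χ², 1 df, **no continuity
  correction** (this choice reproduces the printed significance bands; the
  χ²-equals-z² identity is property-tested).
- The crude odds ratio is the cross-product with a log-scale Wald 95 % CI.
  A zero cell triggers the Haldane–Anscombe +0.5 on every cell and a flag in
  the output — the corrected estimate is never silently presented as exact.
- The cluster-robust odds ratio is a population-averaged logistic GEE
  (binomial family, logit link, independence working correlation, sandwich
  variance clustered by assessor), via `statsmodels`. With a single binary
  covariate the GEE point estimate coincides with the crude OR of the
  collapsed table for *any* clustering — verified on random clustered
  datasets — so published GEE point estimates are recomputable from printed
  counts even though the unpublished cluster structure makes the published
  CIs and p-values non-reproducible. They are accordingly not reproduction
  targets; the same applies to the published timing CI, whose printed
  denominators are not fully recoverable.
- Completion times compare by two-sided t-test, Welch by default (the
  source is silent on pooling; Welch is the safer default and a pooled
  option exists).
- Table rendering rounds half-up to one decimal, matching printed style;
  internal computation is never rounded.

## Synthetic cohort

`generate_cohort` draws each condition's gold label from its prevalence and
then samples the underlying measurement from the matching side of the
threshold, with safety margins (≥ 0.1 °C, ≥ 0.2 weight-loss percentage
points, ±0.5 mm/g on integer rounding) so that gram rounding and °F→°C
conversion cannot flip a label. Every infant is re-classified at generation
time and regenerated on the (rare) mismatch, so `classify_case(case) ≡ gold`
holds exhaustively, by construction *and* by check.

Default parameters are the reference study's expert-classification column:
prevalences (e.g. poor feeding 0.619, small 0.488, fever 0.155, hypothermia
0.060, feeding intolerance 0.083), postnatal age ~ N(6.5, 6.7²) truncated to
[0, 27] days, gestational age ~ N(40.1, 3.2²) weeks, 31 % female. Values the
source does not state and that were chosen once here: LMP recorded with
probability 0.33 (the observed share of encounters with an LMP on file),
10 % of temperatures entered in °F, measurement windows adjacent to each
threshold (e.g. fever → uniform(38.2, 40.0) °C, severe small-infant loss →
uniform(10.3, 16) %). Within each size stratum the very-low-weight label is
nested inside low-birth-weight, and foot-length-only small infants fill the
gap between the small and LBW prevalences.

## Assessor-error simulation

The crossover design is replayed literally: assessors with even ID numbers
start mobile, odd start paper, everyone alternates after each block of six.
Per condition the call matches gold with probability `sensitivity` (gold
positive) or `specificity` (gold negative), shifted on the log-odds scale by
a per-assessor N(0, σ²) random effect (default σ = 0.3). The shipped
calibration sets sensitivity = specificity = the published per-method
correct proportion for each condition, because the published tables report
only overall correctness — the config is labeled as a calibration, not
truth.

The two weight-loss conditions are simulated as one categorical call over
{none, moderate, severe} whose marginals match the two configured
per-condition accuracies, clipped to the feasible simplex — independent
flips could assert severe and moderate loss simultaneously, which no
coherent assessor can. `implied_correct_proportions` computes the exact
proportions this scheme implies (Gauss–Hermite integration over the random
effect, same clipping), and the parameter-recovery test checks the simulated
study against those implied values, with a tolerance combining binomial and
between-assessor variance.

Record-field missingness (paper arm only) and call accuracy are *separate
processes*: a paper assessor may classify fever yet never write the
temperature down, which is exactly the pattern the reference study reports
(temperature recorded 59.6 % of the time while fever calls exist for every
encounter). Marginal missingness rates are the published ones
(RR 0.548, temperature 0.404, weight 0.029, weight-loss calculation 0.048,
gestational age 0.793, postnatal age 0.260, recommendation 0.673, and 0.25
per condition item). Fields are dropped independently, so the *joint*
full-completion rate of simulated paper records is lower than the published
23.8 % — the marginals alone cannot reproduce the joint figure without a
dependence model, which is out of scope; the published completeness
arithmetic is instead checked against fixture records that reconstruct the
printed marginal counts directly. Completion times are truncated normals
with the published means/SDs (17.5 ± 10.8 vs 23.6 ± 11.6 min).

Three independent RNG streams (cohort, error, missingness) are spawned from
the one seed, so changing, say, a missingness rate does not perturb the
cohort draw.

### What the simulator does not emulate

Assessor learning over the study, site differences (hospital vs field),
the day-one form revision (the audit fixture handles its denominator effect
directly), correlated field missingness within a record, and
measurement-level error on the mobile arm (mobile errors enter at the call
level, per the calibration, not as mis-typed grams). Passing recovery tests
therefore show the pipeline is internally consistent at the study's scale,
not that real CHW error behaves like the model.

## Problem sizes and numerics

The bundled checks run at: 10 000 random cases for the oracle
cross-check, 10 000 infants for prevalence recovery (3 binomial SEs),
500 infants × 2 assessments for error-model recovery, 100 random clustered
datasets for the GEE/crude identity (relative tolerance 10⁻⁴, the GEE
optimizer's precision), and 85-infant studies for end-to-end smoke runs —
sizes chosen to make stochastic bounds tight while keeping the whole suite
in seconds. Degenerate inputs are handled explicitly: zero-margin 2×2
tables report the test undefined rather than raising mid-pipeline, zero
cells flag the corrected OR, single-cluster GEE warns, and empty method
arms raise immediately.
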