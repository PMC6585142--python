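# neocds — newborn clinical decision support and diagnostic-accuracy evaluation

In low-resource settings, community health workers (CHWs) are often the first
to assess newborns, using checklist-style (IMCI/CNCP-family) paper forms.
Mobile decision-support apps promise more complete assessments and more
accurate classification of newborn danger signs. `neocds` is a desk
implementation of that whole problem: it reproduces the *algorithmic content*
of such an app and the *statistics* of a method-comparison study, so that the
classification rules, the form mechanics, and the evaluation arithmetic can
be tested, varied and simulated end to end.

It is intended for biostatisticians and digital-health researchers who want
a transparent, configurable reference implementation of:

- **the diagnostic rule engine** — tri-state (positive / negative /
  not-assessable) classification of 18 newborn conditions from raw
  observations: low birth weight (< 2500 g), small infant (< 2500 g or foot
  length < 74 mm), very low weight (< 1500 g), size-dependent weight-loss
  bands (8–10 % moderate / > 10 % severe for small infants; 10–15 % / > 15 %
  otherwise), fever (> 38.0 °C), hypothermia (< 35.5 °C), fast breathing
  (> 60 breaths/min), directly observed danger signs, and two any-of-five
  feeding composites;
- **case management** — the single-danger-sign referral rule with lower
  thresholds for small infants, a condition → counseling mapping (kangaroo
  mother care, cup feeding, increased feeding frequency, …), and follow-up
  scheduling (+2 days small/moderate, +7 days routine);
- **the form engine** — ordered items, skip logic, range constraints,
  required double entry, computed fields, and the completeness audit that
  distinguishes an engine-enforced (mobile-style) record from a free-text
  (paper-style) one;
- **the evaluation statistics** — per-condition 2×2 tables of correct
  classification against a gold-standard assessor, Pearson χ² (no continuity
  correction), percentage-point differences, crude odds ratios with Wald
  CIs, cluster-robust (GEE, logit link, independence working correlation)
  odds ratios clustered by assessor, and Welch t-tests on completion times;
- **a synthetic study generator** — cohorts whose raw measurements are
  consistent with their gold labels *by construction*, plus a crossover
  assessor-error simulator (blocks of six assessments, alternating methods,
  per-CHW random effects, paper-method field missingness).

## Worked example

```python
from datetime import date, datetime
from neocds import InfantCase, TriState, classify_case, build_plan, summary_report
from neocds.core import DANGER_SIGN_ITEMS, FEEDING_INTOLERANCE_ITEMS, BREASTFEEDING_ITEMS

case = InfantCase(
    infant_id="demo",
    birth_datetime=datetime(2017, 3, 1, 8, 0),
    assessment_datetime=datetime(2017, 3, 7, 10, 0),
    lmp_date=date(2016, 6, 22),                      # 36.0 weeks -> preterm
    birth_weight_g=2300, current_weight_g=2080,      # small; 9.6 % loss
    foot_length_mm=72, temperature_value=35.2,       # short foot; hypothermia
    breath_count_60s=48,
    signs={k: TriState.absent for k in DANGER_SIGN_ITEMS},
    feeding_intolerance_items={k: TriState.absent for k in FEEDING_INTOLERANCE_ITEMS},
    breastfeeding_items={k: TriState.present for k in BREASTFEEDING_ITEMS},
)
profile = classify_case(case)
plan = build_plan(profile, case.assessment_datetime.date())
print(summary_report(case, profile, plan))
```

prints

```
ASSESSMENT SUMMARY — infant demo
Conditions identified:
  - low birth weight
  - small
  - moderate weight loss
  - hypothermia
Small baby: apply small-baby care (warmth, feeding support).
Counseling:
  - increase feeding frequency
  - kangaroo mother care
  - thermal care
REFER to facility now. Reasons: small, moderate weight loss, hypothermia
```

i.e. the 2300 g / 72 mm infant classifies as small, the 9.6 % loss falls in
the small-infant moderate band [8, 10] %, 35.2 °C < 35.5 °C is hypothermia
(a danger sign, hence referral — which supersedes any follow-up date), and
the small + moderate-loss combination also fires the lower small-infant
referral threshold.

A whole synthetic study runs from the command line:

```bash
neocds run --seed 11 --out study/
# -> study/cases.csv gold.csv records.csv labeled.csv completeness.csv comparison.csv report.txt
```

`comparison.csv` holds one row per condition with correct/total counts by
method, proportions, percentage-point difference, χ² p-value, and the odds
ratio of correct classification with its cluster-robust CI.

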