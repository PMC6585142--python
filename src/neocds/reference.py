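"""Published per-method counts from the reference field study, and the
recomputation of its summary statistics from those counts.

The study compared community health workers assessing newborns with a
mobile decision-support app versus an equivalent paper form, each call
judged against a gold-standard assessor.  Its published tables print, per
condition, the correct/total counts by method; everything downstream of
those counts (proportions, percentage-point differences, chi-squared tests,
odds ratios) is recomputed here by this package's own statistics — the
counts are the inputs, the statistics are never copied.

Completeness counts follow the same pattern: recorded/total per audit flag
by method (full assessments are audited only on the study days on which the
paper form distinguished "assessed, negative" from "not assessed", hence
the smaller denominator on that row).
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from neocds.evaluate import (
    TwoByTwo,
    compare_proportions,
    crude_odds_ratio,
    round_half_up,
)

__all__ = [
    "reference_classification_counts",
    "reference_completeness_counts",
    "reproduce_classification_comparison",
    "reproduce_completeness_comparison",
    "completeness_fixture_records",
]


def _read_csv(name: str) -> pd.DataFrame:
    text = resources.files("neocds").joinpath(f"data/{name}").read_text()
    return pd.read_csv(StringIO(text))


def reference_classification_counts() -> pd.DataFrame:
    """Per-condition correct/total counts by method (printed inputs)."""
    return _read_csv("reference_classification_counts.csv")


def reference_completeness_counts() -> pd.DataFrame:
    """Per-flag recorded/total counts by method (printed inputs)."""
    return _read_csv("reference_completeness_counts.csv")


def reproduce_classification_comparison() -> pd.DataFrame:
    """Recompute the per-condition method comparison from the printed counts:
    proportions, percentage-point difference, chi-squared p, and crude odds
    ratio with Wald CI (the study's GEE point estimates are crude-equivalent
    for a single binary covariate)."""
    counts = reference_classification_counts()
    rows = []
    for r in counts.itertuples(index=False):
        table = TwoByTwo(
            correct_mobile=int(r.correct_mobile),
            incorrect_mobile=int(r.n_mobile - r.correct_mobile),
            correct_paper=int(r.correct_paper),
            incorrect_paper=int(r.n_paper - r.correct_paper),
        )
        comp = compare_proportions(table)
        orr = crude_odds_ratio(table)
        rows.append(
            {
                "condition": r.condition,
                "prop_paper": 100.0 * comp.prop_paper,
                "prop_mobile": 100.0 * comp.prop_mobile,
                "ppd": round_half_up(comp.ppd),
                "chi2_p": comp.chi2_p,
                "or": round_half_up(orr.point),
                "or_low": orr.ci_low,
                "or_high": orr.ci_high,
                "or_corrected": orr.corrected,
            }
        )
    return pd.DataFrame(rows)


def completeness_fixture_records() -> list:
    """Synthetic assessment records reconstructing the printed completeness
    marginals for the two rows the audit pipeline is checked against: full
    completion (20/84 paper vs 86/86 mobile) and gestational-age calculation
    among LMP-recorded encounters (6/29 paper vs 34/34 mobile).

    The raw study records are unpublished; these stand-ins carry only the
    structure the completeness audit reads (recorded answers, recommendation
    presence), so the published proportions are *recomputed* by running
    :func:`neocds.evaluate.completeness_table` over them.
    """
    from datetime import datetime

    from neocds.forms import FULL_ASSESSMENT_SIGN_ITEMS, AssessmentRecord

    def record(method, idx, complete, lmp, ga):
        answers = {s: "no" for s in FULL_ASSESSMENT_SIGN_ITEMS}
        answers.update(
            {
                "birth_weight_g": 3000,
                "temperature_value": 37.0,
                "breath_count_60s": 45,
                "weight_change_percent": -1.0,
                "postnatal_age_days": 5,
            }
        )
        if not complete:
            del answers["breath_count_60s"]  # RR unrecorded breaks full completion
            del answers[FULL_ASSESSMENT_SIGN_ITEMS[0]]
        if lmp:
            answers["lmp_date"] = "2016-06-15"
            if ga:
                answers["gestational_age_weeks"] = 40.0
        t = datetime(2017, 3, 20, 9, 0)
        return AssessmentRecord(
            method=method,
            chw_id=f"CHW{idx % 12:02d}",
            infant_id=f"F{method[0]}{idx:03d}",
            answers=answers,
            recommendations=["follow-up"],
            start_time=t,
            end_time=t,
        )

    records = []
    for i in range(84):  # paper arm: 20 complete; 29 with LMP, 6 with GA done
        records.append(record("paper", i, complete=i < 20, lmp=i < 29, ga=i < 6))
    for i in range(86):  # mobile arm: complete by construction; 34 with LMP+GA
        records.append(record("mobile", i, complete=True, lmp=i < 34, ga=True))
    return records


def reproduce_completeness_comparison() -> pd.DataFrame:
    """Recompute the completeness table statistics from the printed counts."""
    counts = reference_completeness_counts()
    rows = []
    for r in counts.itertuples(index=False):
        table = TwoByTwo(
            correct_mobile=int(r.k_mobile),
            incorrect_mobile=int(r.n_mobile - r.k_mobile),
            correct_paper=int(r.k_paper),
            incorrect_paper=int(r.n_paper - r.k_paper),
        )
        comp = compare_proportions(table)
        rows.append(
            {
                "flag": r.flag,
                "prop_paper": round_half_up(100.0 * comp.prop_paper),
                "prop_mobile": round_half_up(100.0 * comp.prop_mobile),
                "ppd": round_half_up(comp.ppd),
                "chi2_p": comp.chi2_p,
            }
        )
    return pd.DataFrame(rows)
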