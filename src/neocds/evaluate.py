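"""Diagnostic-accuracy statistics comparing two assessment methods.

Given per-assessment condition calls labeled against a gold-standard
assessor, this module computes the study-shaped outputs: per-condition
2x2 tables of correct classification by method, proportions and
percentage-point differences, Pearson chi-squared tests (no continuity
correction), crude odds ratios with log-scale Wald confidence intervals,
cluster-robust (GEE) odds ratios accounting for clustering by assessor, and
Welch t-tests on completion times.

Correctness convention: an assessor's call is correct iff it is resolved
(not "not assessable") and equal to the gold call — a missed assessment can
never be correct.

For a population-averaged logistic model with a single binary covariate and
independence working correlation, the GEE point estimate coincides with the
crude odds ratio of the collapsed 2x2 for any clustering; clustering moves
only the variance.  This identity is exercised in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from neocds.classify import CONDITIONS, ConditionProfile, TriResult
from neocds.forms import AssessmentRecord, completeness_report

__all__ = [
    "LabeledAssessment",
    "TwoByTwo",
    "ProportionComparison",
    "OddsRatioResult",
    "MethodComparison",
    "TimeComparison",
    "DegenerateTableError",
    "correctness",
    "label_assessment",
    "condition_2x2",
    "compare_proportions",
    "crude_odds_ratio",
    "cluster_robust_or",
    "mean_time_comparison",
    "study_report",
    "round_half_up",
    "COMPLETENESS_ROWS",
]

Z975 = 1.959963984540054  # two-sided 95% normal quantile


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding, matching printed-table style (not banker's)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class DegenerateTableError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledAssessment:
    """One assessor call on one condition, labeled against the gold call."""

    chw_id: str
    infant_id: str
    method: str  # "mobile" | "paper"
    condition: str
    assessor_call: TriResult
    gold_call: bool

    @property
    def correct(self) -> bool:
        if self.assessor_call is TriResult.not_assessable:
            return False
        return (self.assessor_call is TriResult.positive) == self.gold_call


def correctness(assessor: ConditionProfile, gold: ConditionProfile) -> dict[str, bool]:
    """Per-condition correctness of one assessor profile against gold.

    Conditions the gold assessor could not resolve are omitted (there is no
    truth to compare against); an unresolved *assessor* call counts as
    incorrect.
    """
    if set(assessor.conditions) != set(gold.conditions):
        raise ValueError("assessor and gold profiles cover different condition sets")
    out: dict[str, bool] = {}
    for c in CONDITIONS:
        g = gold[c]
        if g is TriResult.not_assessable:
            continue
        a = assessor[c]
        out[c] = a is not TriResult.not_assessable and a is g
    return out


def label_assessment(
    chw_id: str,
    infant_id: str,
    method: str,
    assessor: ConditionProfile,
    gold: ConditionProfile,
) -> list[LabeledAssessment]:
    """Expand one assessed case into per-condition labeled rows."""
    rows = []
    for c in CONDITIONS:
        g = gold[c]
        if g is TriResult.not_assessable:
            continue
        rows.append(
            LabeledAssessment(
                chw_id=chw_id,
                infant_id=infant_id,
                method=method,
                condition=c,
                assessor_call=assessor[c],
                gold_call=g is TriResult.positive,
            )
        )
    return rows


@dataclass(frozen=True)
class TwoByTwo:
    """Method x correct counts for one condition."""

    correct_mobile: int
    incorrect_mobile: int
    correct_paper: int
    incorrect_paper: int

    @property
    def n_mobile(self) -> int:
        return self.correct_mobile + self.incorrect_mobile

    @property
    def n_paper(self) -> int:
        return self.correct_paper + self.incorrect_paper

    @property
    def prop_mobile(self) -> float:
        return self.correct_mobile / self.n_mobile

    @property
    def prop_paper(self) -> float:
        return self.correct_paper / self.n_paper

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.correct_mobile, self.incorrect_mobile],
                [self.correct_paper, self.incorrect_paper],
            ],
            dtype=float,
        )


def condition_2x2(labeled: Iterable[LabeledAssessment], condition: str) -> TwoByTwo:
    cm = im = cp = ip = 0
    for row in labeled:
        if row.condition != condition:
            continue
        if row.method == "mobile":
            cm, im = cm + row.correct, im + (not row.correct)
        elif row.method == "paper":
            cp, ip = cp + row.correct, ip + (not row.correct)
        else:
            raise ValueError(f"unknown method {row.method!r}")
    table = TwoByTwo(cm, im, cp, ip)
    if table.n_mobile == 0 or table.n_paper == 0:
        raise DegenerateTableError(f"no records for one method on {condition!r}")
    return table


@dataclass(frozen=True)
class ProportionComparison:
    prop_mobile: float
    prop_paper: float
    ppd: float  # percentage points, mobile - paper
    chi2_stat: float
    chi2_p: float
    defined: bool = True  # False when a zero margin makes the test undefined


def compare_proportions(table: TwoByTwo) -> ProportionComparison:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2, plus
    the percentage-point difference in correct proportions."""
    if table.n_mobile == 0 or table.n_paper == 0:
        raise DegenerateTableError("empty method arm")
    ppd = 100.0 * (table.prop_mobile - table.prop_paper)
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any():
        return ProportionComparison(
            table.prop_mobile, table.prop_paper, ppd, float("nan"), float("nan"), defined=False
        )
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return ProportionComparison(table.prop_mobile, table.prop_paper, ppd, float(chi2), float(p))


@dataclass(frozen=True)
class OddsRatioResult:
    point: float
    ci_low: float
    ci_high: float
    p: Optional[float] = None
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to all cells


def crude_odds_ratio(table: TwoByTwo) -> OddsRatioResult:
    """Cross-product odds ratio of correct classification, mobile vs paper,
    with a log-scale Wald 95% CI.  A zero cell triggers the Haldane-Anscombe
    0.5 correction on every cell, flagged in the result."""
    a, b = table.correct_mobile, table.incorrect_mobile
    c, d = table.correct_paper, table.incorrect_paper
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(point)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return OddsRatioResult(
        point=point,
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p=float(p),
        corrected=corrected,
    )


def _labeled_frame(labeled: Iterable[LabeledAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chw_id": [r.chw_id for r in labeled],
            "method": [r.method for r in labeled],
            "condition": [r.condition for r in labeled],
            "correct": [int(r.correct) for r in labeled],
        }
    )


def cluster_robust_or(
    data: pd.DataFrame,
    outcome: str = "correct",
    method_col: str = "method",
    cluster_col: str = "chw_id",
) -> OddsRatioResult:
    """Population-averaged logistic fit (GEE, binomial family, logit link,
    independence working correlation) of correctness on method, with
    sandwich cluster-robust variance by assessor.

    The point estimate equals the crude odds ratio of the collapsed table;
    the CI and p-value respond to the clustering.
    """
    import statsmodels.api as sm

    df = data[[outcome, method_col, cluster_col]].copy()
    n_clusters = df[cluster_col].nunique()
    if n_clusters < 2:
        warnings.warn("robust variance is unreliable with a single cluster", stacklevel=2)
    x = (df[method_col] == "mobile").astype(float)
    exog = sm.add_constant(pd.DataFrame({"mobile": x}))
    model = sm.GEE(
        df[outcome].astype(float),
        exog,
        groups=df[cluster_col],
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Independence(),
    )
    res = model.fit()
    beta = float(res.params["mobile"])
    se = float(res.bse["mobile"])
    p = float(res.pvalues["mobile"])
    return OddsRatioResult(
        point=math.exp(beta),
        ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se),
        p=p,
    )


@dataclass(frozen=True)
class TimeComparison:
    mean_mobile: float
    mean_paper: float
    diff: float  # mobile - paper, minutes
    ci_low: float
    ci_high: float
    p: float


def mean_time_comparison(
    times_mobile: Sequence[float],
    times_paper: Sequence[float],
    equal_var: bool = False,
) -> TimeComparison:
    """Two-sided two-sample t-test (Welch by default) of completion times in
    minutes, with a 95% CI for the mean difference."""
    a = np.asarray(times_mobile, dtype=float)
    b = np.asarray(times_paper, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per arm")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    diff = a.mean() - b.mean()
    if equal_var:
        dof = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / dof
        se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        se = math.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    tq = stats.t.ppf(0.975, dof)
    return TimeComparison(
        mean_mobile=float(a.mean()),
        mean_paper=float(b.mean()),
        diff=float(diff),
        ci_low=float(diff - tq * se),
        ci_high=float(diff + tq * se),
        p=float(p),
    )


@dataclass(frozen=True)
class MethodComparison:
    """One rendered comparison-table row for one condition."""

    condition: str
    correct_paper: int
    n_paper: int
    correct_mobile: int
    n_mobile: int
    prop_paper: float
    prop_mobile: float
    ppd: float
    chi2_stat: float
    chi2_p: float
    or_point: float
    or_ci: tuple[float, float]
    or_p: Optional[float]
    or_corrected: bool


COMPLETENESS_ROWS = (
    "full_assessment",
    "any_recommendation",
    "rr_recorded",
    "temp_recorded",
    "weight_recorded",
    "weight_loss_calculated",
    "ga_calculated_if_lmp",
    "postnatal_age_calculated",
)


def completeness_table(records: Iterable[AssessmentRecord]) -> pd.DataFrame:
    """Per-flag completeness counts by method, with percentage-point
    differences and chi-squared p-values (the completeness-audit table).

    The gestational-age row's denominator is restricted to records where an
    LMP was on file.
    """
    flags = [(r.method, completeness_report(r)) for r in records]
    rows = []
    for flag in COMPLETENESS_ROWS:
        counts = {}
        for method in ("paper", "mobile"):
            vals = [getattr(f, flag) for m, f in flags if m == method]
            vals = [v for v in vals if v is not None]  # GA row: LMP subset
            counts[method] = (sum(vals), len(vals))
        (kp, np_), (km, nm) = counts["paper"], counts["mobile"]
        if np_ == 0 or nm == 0:
            rows.append(
                {
                    "flag": flag,
                    "k_paper": kp,
                    "n_paper": np_,
                    "k_mobile": km,
                    "n_mobile": nm,
                    "prop_paper": float("nan"),
                    "prop_mobile": float("nan"),
                    "ppd": float("nan"),
                    "chi2_p": float("nan"),
                }
            )
            continue
        table = TwoByTwo(km, nm - km, kp, np_ - kp)
        comp = compare_proportions(table)
        rows.append(
            {
                "flag": flag,
                "k_paper": kp,
                "n_paper": np_,
                "k_mobile": km,
                "n_mobile": nm,
                "prop_paper": 100.0 * comp.prop_paper,
                "prop_mobile": 100.0 * comp.prop_mobile,
                "ppd": comp.ppd,
                "chi2_p": comp.chi2_p,
            }
        )
    return pd.DataFrame(rows)


def comparison_table(
    labeled: Sequence[LabeledAssessment],
    use_gee: bool = True,
    conditions: Sequence[str] = CONDITIONS,
) -> pd.DataFrame:
    """Per-condition method comparison: counts, proportions, percentage-point
    difference, chi-squared, and odds ratio of correct classification.

    The OR point estimate is always the crude cross-product; when labeled
    data span >= 2 assessor clusters and ``use_gee`` is set, the CI and
    p-value come from the cluster-robust GEE fit instead of the Wald CI.
    """
    df = _labeled_frame(labeled) if labeled else pd.DataFrame(columns=["condition"])
    rows = []
    for condition in conditions:
        table = condition_2x2(labeled, condition)
        comp = compare_proportions(table)
        orr = crude_odds_ratio(table)
        ci, or_p = (orr.ci_low, orr.ci_high), orr.p
        sub = df[df["condition"] == condition]
        if use_gee and not orr.corrected and sub["chw_id"].nunique() >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gee = cluster_robust_or(sub)
                ci, or_p = (gee.ci_low, gee.ci_high), gee.p
            except Exception:  # separation etc.: keep the Wald interval
                pass
        rows.append(
            MethodComparison(
                condition=condition,
                correct_paper=table.correct_paper,
                n_paper=table.n_paper,
                correct_mobile=table.correct_mobile,
                n_mobile=table.n_mobile,
                prop_paper=100.0 * comp.prop_paper,
                prop_mobile=100.0 * comp.prop_mobile,
                ppd=comp.ppd,
                chi2_stat=comp.chi2_stat,
                chi2_p=comp.chi2_p,
                or_point=orr.point,
                or_ci=ci,
                or_p=or_p,
                or_corrected=orr.corrected,
            )
        )
    out = pd.DataFrame(
        {
            "condition": [r.condition for r in rows],
            "correct_paper": [r.correct_paper for r in rows],
            "n_paper": [r.n_paper for r in rows],
            "prop_paper": [r.prop_paper for r in rows],
            "correct_mobile": [r.correct_mobile for r in rows],
            "n_mobile": [r.n_mobile for r in rows],
            "prop_mobile": [r.prop_mobile for r in rows],
            "ppd": [r.ppd for r in rows],
            "chi2_p": [r.chi2_p for r in rows],
            "or": [r.or_point for r in rows],
            "or_low": [r.or_ci[0] for r in rows],
            "or_high": [r.or_ci[1] for r in rows],
            "or_p": [r.or_p for r in rows],
            "or_corrected": [r.or_corrected for r in rows],
        }
    )
    return out


def render_comparison_text(df: pd.DataFrame) -> str:
    """Fixed-width text rendering with the printed-table rounding style
    (half-up, one decimal)."""
    lines = [
        f"{'condition':32s} {'paper':>12s} {'mobile':>12s} {'ppd':>7s} {'OR':>7s} {'95% CI':>16s}"
    ]
    for _, r in df.iterrows():
        paper = f"{r.correct_paper}/{r.n_paper} ({round_half_up(r.prop_paper):.1f}%)"
        mobile = f"{r.correct_mobile}/{r.n_mobile} ({round_half_up(r.prop_mobile):.1f}%)"
        flag = "*" if r.or_corrected else ""
        ci = f"({round_half_up(r.or_low):.1f}, {round_half_up(r.or_high):.1f}){flag}"
        lines.append(
            f"{r.condition:32s} {paper:>12s} {mobile:>12s} "
            f"{round_half_up(r.ppd):>7.1f} {round_half_up(r['or']):>7.1f} {ci:>16s}"
        )
    return "\n".join(lines)


def render_completeness_text(df: pd.DataFrame) -> str:
    lines = [f"{'completeness flag':28s} {'paper':>16s} {'mobile':>16s} {'ppd':>7s}"]
    for _, r in df.iterrows():
        paper = f"{r.k_paper}/{r.n_paper} ({round_half_up(r.prop_paper):.1f}%)"
        mobile = f"{r.k_mobile}/{r.n_mobile} ({round_half_up(r.prop_mobile):.1f}%)"
        lines.append(f"{r.flag:28s} {paper:>16s} {mobile:>16s} {round_half_up(r.ppd):>7.1f}")
    return "\n".join(lines)


def study_report(
    records: Sequence[AssessmentRecord],
    labeled: Sequence[LabeledAssessment],
    use_gee: bool = True,
) -> dict:
    """The full study output: completeness table, per-condition comparison
    table, and their text renderings."""
    comp = completeness_table(records)
    comparison = comparison_table(labeled, use_gee=use_gee)
    return {
        "completeness": comp,
        "comparison": comparison,
        "text": (
            "COMPLETENESS OF ASSESSMENTS\n"
            + render_completeness_text(comp)
            + "\n\nCORRECT CLASSIFICATION BY METHOD\n"
            + render_comparison_text(comparison)
        ),
    }
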