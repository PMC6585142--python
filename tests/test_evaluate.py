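import math
import random

import numpy as np
import pandas as pd
import pytest

from neocds.classify import TriResult
from neocds.evaluate import (
    DegenerateTableError,
    LabeledAssessment,
    TwoByTwo,
    cluster_robust_or,
    compare_proportions,
    condition_2x2,
    correctness,
    crude_odds_ratio,
    mean_time_comparison,
    round_half_up,
)

from _oracles import pearson_chi2_2x2, two_proportion_z, welch_t
from conftest import make_profile


def test_correctness_identity_and_disagreement():
    gold = make_profile(positive=["fever", "small"])
    assert all(correctness(gold, gold).values())

    wrong = make_profile(positive=["small"])  # missed the fever
    res = correctness(wrong, gold)
    assert res["fever"] is False and res["small"] is True


def test_unassessed_call_counts_as_incorrect():
    gold = make_profile()
    assessor = make_profile(na=["hypothermia"])
    assert correctness(assessor, gold)["hypothermia"] is False
    row = LabeledAssessment("c", "i", "paper", "hypothermia", TriResult.not_assessable, False)
    assert row.correct is False


def test_gold_unassessable_conditions_are_excluded():
    gold = make_profile(na=["severe_weight_loss", "moderate_weight_loss"])
    res = correctness(make_profile(), gold)
    assert "severe_weight_loss" not in res and "moderate_weight_loss" not in res


def _labeled(n_correct_m, n_m, n_correct_p, n_p, condition="small"):
    rows = []
    for i in range(n_m):
        rows.append(
            LabeledAssessment(
                f"c{i%3}", f"i{i}", "mobile", condition,
                TriResult.positive if i < n_correct_m else TriResult.negative, True,
            )
        )
    for i in range(n_p):
        rows.append(
            LabeledAssessment(
                f"c{i%3}", f"p{i}", "paper", condition,
                TriResult.positive if i < n_correct_p else TriResult.negative, True,
            )
        )
    return rows


def test_condition_2x2_counting_oracle():
    rnd = random.Random(3)
    for _ in range(25):
        cm, im = rnd.randint(0, 30), rnd.randint(0, 30)
        cp, ip = rnd.randint(0, 30), rnd.randint(0, 30)
        if cm + im == 0 or cp + ip == 0:
            continue
        table = condition_2x2(_labeled(cm, cm + im, cp, cp + ip), "small")
        assert (table.correct_mobile, table.incorrect_mobile) == (cm, im)
        assert (table.correct_paper, table.incorrect_paper) == (cp, ip)


def test_condition_2x2_degenerate_without_both_methods():
    with pytest.raises(DegenerateTableError):
        condition_2x2(_labeled(5, 5, 0, 0), "small")


def test_reference_small_condition_counts():
    table = TwoByTwo(83, 3, 48, 36)
    comp = compare_proportions(table)
    assert round_half_up(comp.ppd) == 39.4
    assert comp.chi2_p < 0.001
    assert round_half_up(crude_odds_ratio(table).point) == 20.8


def test_equal_proportions_give_zero_chi2():
    comp = compare_proportions(TwoByTwo(10, 10, 10, 10))
    assert comp.ppd == 0.0
    assert comp.chi2_stat == pytest.approx(0.0)


def test_chi2_matches_textbook_formula():
    table = TwoByTwo(86, 0, 20, 64)
    comp = compare_proportions(table)
    assert comp.chi2_stat == pytest.approx(pearson_chi2_2x2(86, 0, 20, 64))


def test_chi2_equals_squared_two_proportion_z():
    rnd = random.Random(7)
    for _ in range(100):
        n1, n2 = rnd.randint(5, 80), rnd.randint(5, 80)
        k1, k2 = rnd.randint(1, n1 - 1), rnd.randint(1, n2 - 1)
        comp = compare_proportions(TwoByTwo(k1, n1 - k1, k2, n2 - k2))
        z = two_proportion_z(k1, n1, k2, n2)
        assert comp.chi2_stat == pytest.approx(z**2, rel=1e-9)


def test_zero_margin_reported_undefined():
    comp = compare_proportions(TwoByTwo(10, 0, 5, 0))
    assert not comp.defined and math.isnan(comp.chi2_stat)


@pytest.mark.parametrize(
    "table, expected",
    [
        (TwoByTwo(83, 3, 48, 36), 20.8),
        (TwoByTwo(84, 2, 62, 22), 14.9),
        (TwoByTwo(10, 10, 10, 10), 1.0),
    ],
)
def test_crude_odds_ratio_values(table, expected):
    assert round_half_up(crude_odds_ratio(table).point) == expected


def test_zero_cell_triggers_flagged_correction():
    res = crude_odds_ratio(TwoByTwo(20, 0, 10, 10))
    assert res.corrected is True
    assert np.isfinite(res.point) and res.point > 1


def test_or_symmetry_under_method_swap():
    rnd = random.Random(13)
    for _ in range(50):
        a, b, c, d = (rnd.randint(1, 40) for _ in range(4))
        fwd = crude_odds_ratio(TwoByTwo(a, b, c, d))
        rev = crude_odds_ratio(TwoByTwo(c, d, a, b))
        assert fwd.point == pytest.approx(1 / rev.point)
        assert fwd.ci_low == pytest.approx(1 / rev.ci_high)
        assert fwd.ci_high == pytest.approx(1 / rev.ci_low)


def _random_clustered(rnd, n_clusters, n_obs):
    rows = []
    for _ in range(n_obs):
        rows.append(
            {
                "chw_id": f"c{rnd.randrange(n_clusters)}",
                "method": rnd.choice(["mobile", "paper"]),
                "correct": rnd.random() < 0.7,
            }
        )
    return pd.DataFrame(rows)


def _collapse(df):
    cm = int(((df.method == "mobile") & df.correct).sum())
    im = int(((df.method == "mobile") & ~df.correct).sum())
    cp = int(((df.method == "paper") & df.correct).sum())
    ip = int(((df.method == "paper") & ~df.correct).sum())
    return TwoByTwo(cm, im, cp, ip)


def test_gee_point_estimate_equals_crude_or():
    """The cluster-robust fit's point estimate must collapse to the crude
    cross-product for any clustering."""
    rnd = random.Random(99)
    checked = 0
    while checked < 20:
        df = _random_clustered(rnd, rnd.randint(2, 5), rnd.randint(30, 60))
        table = _collapse(df)
        if 0 in (table.correct_mobile, table.incorrect_mobile, table.correct_paper, table.incorrect_paper):
            continue
        gee = cluster_robust_or(df)
        crude = crude_odds_ratio(table)
        assert gee.point == pytest.approx(crude.point, rel=1e-4)
        checked += 1


def test_single_observation_clusters_match_plain_robust_wald():
    rnd = random.Random(5)
    rows = [
        {"chw_id": f"solo{i}", "method": ("mobile" if i % 2 else "paper"), "correct": rnd.random() < 0.6}
        for i in range(60)
    ]
    df = pd.DataFrame(rows)
    table = _collapse(df)
    if 0 in (table.correct_mobile, table.incorrect_mobile, table.correct_paper, table.incorrect_paper):
        pytest.skip("degenerate draw")
    gee = cluster_robust_or(df)
    # with one observation per cluster the sandwich reduces to HC robust
    import statsmodels.api as sm

    x = sm.add_constant(pd.DataFrame({"mobile": (df.method == "mobile").astype(float)}))
    logit = sm.Logit(df.correct.astype(float), x).fit(disp=0, cov_type="HC0")
    assert gee.point == pytest.approx(math.exp(logit.params["mobile"]), rel=1e-4)
    assert math.log(gee.ci_high / gee.ci_low) == pytest.approx(
        2 * 1.959963984540054 * logit.bse["mobile"], rel=0.05
    )


def test_single_cluster_warns():
    df = pd.DataFrame(
        {
            "chw_id": ["c0"] * 40,
            "method": ["mobile", "paper"] * 20,
            "correct": [True, False, True, True] * 10,
        }
    )
    with pytest.warns(UserWarning, match="single cluster"):
        cluster_robust_or(df)


def test_mean_time_identical_samples():
    res = mean_time_comparison([10, 12, 14], [10, 12, 14])
    assert res.diff == 0.0
    assert res.p == pytest.approx(1.0)


def test_welch_t_matches_hand_formula():
    xs, ys = [17.0, 19.5, 15.2, 21.0, 16.6], [22.0, 25.1, 23.9, 20.4]
    res = mean_time_comparison(xs, ys)
    t = welch_t(xs, ys)
    assert res.diff == pytest.approx(sum(xs) / 5 - sum(ys) / 4)
    se = res.diff / t
    assert (res.ci_high - res.ci_low) > 0
    assert res.p < 1
    assert res.diff / se == pytest.approx(t)


def test_mean_difference_reported_in_minutes():
    rng = np.random.default_rng(4)
    mobile = rng.normal(17.5, 1.0, 200)
    paper = rng.normal(23.6, 1.0, 200)
    res = mean_time_comparison(mobile, paper)
    assert res.diff == pytest.approx(-6.1, abs=0.4)
    assert res.ci_low < res.diff < res.ci_high


def test_round_half_up_matches_printed_style():
    assert round_half_up(20.75) == 20.8
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(-15.85) == -15.9
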