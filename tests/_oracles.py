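"""Independent brute-force oracles used to cross-check the package.

Deliberately written from the guideline definitions with literal thresholds
and no reuse of package internals: each function re-derives its answer the
long way so agreement with the package is evidence, not tautology.
"""

from __future__ import annotations

import math

from neocds.core import (
    BREASTFEEDING_ITEMS,
    DANGER_SIGN_ITEMS,
    FEEDING_INTOLERANCE_ITEMS,
    InfantCase,
    TriState,
)

POS, NEG, NA = "positive", "negative", "na"


def brute_force_classify(case: InfantCase) -> dict[str, str]:
    """Re-derive every condition with literal guideline thresholds."""
    out: dict[str, str] = {}

    bw, cw, fl = case.birth_weight_g, case.current_weight_g, case.foot_length_mm

    out["low_birth_weight"] = NA if bw is None else (POS if bw < 2500 else NEG)

    crits = []
    if bw is not None:
        crits.append(bw < 2500)
    if fl is not None:
        crits.append(fl < 74)
    out["small"] = NA if not crits else (POS if any(crits) else NEG)

    ws = [w for w in (bw, cw) if w is not None]
    out["very_low_weight_lt1500"] = NA if not ws else (POS if min(ws) < 1500 else NEG)

    if bw is None or cw is None:
        out["severe_weight_loss"] = NA
        out["moderate_weight_loss"] = NA
    else:
        loss = 100.0 * (bw - cw) / bw
        small = out["small"] == POS  # unknown size graded with non-small bands
        if small:
            sev, mod_lo, mod_hi = loss > 10, 8, 10
        else:
            sev, mod_lo, mod_hi = loss > 15, 10, 15
        out["severe_weight_loss"] = POS if sev else NEG
        out["moderate_weight_loss"] = POS if (not sev and mod_lo <= loss <= mod_hi) else NEG

    if case.temperature_value is None:
        out["fever"] = out["hypothermia"] = NA
    else:
        t = case.temperature_value
        if case.temperature_unit.value == "F":
            t = (t - 32) * 5 / 9
        t = round(t, 1)
        out["fever"] = POS if t > 38.0 else NEG
        out["hypothermia"] = POS if t < 35.5 else NEG

    rr = case.breath_count_60s
    out["fast_breathing"] = NA if rr is None else (POS if rr > 60 else NEG)

    for sign in DANGER_SIGN_ITEMS:
        v = case.signs[sign]
        out[sign] = NA if v is TriState.not_assessed else (POS if v is TriState.present else NEG)

    fi = [case.feeding_intolerance_items[k] for k in FEEDING_INTOLERANCE_ITEMS]
    if any(v is TriState.present for v in fi):
        out["feeding_intolerance"] = POS
    elif all(v is TriState.absent for v in fi):
        out["feeding_intolerance"] = NEG
    else:
        out["feeding_intolerance"] = NA

    bf = [case.breastfeeding_items[k] for k in BREASTFEEDING_ITEMS]
    if any(v is TriState.absent for v in bf):
        out["breastfeeding_problems"] = POS
    elif all(v is TriState.present for v in bf):
        out["breastfeeding_problems"] = NEG
    else:
        out["breastfeeding_problems"] = NA

    return out


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Textbook Pearson statistic via expected counts, no correction."""
    n = a + b + c + d
    chi2 = 0.0
    for obs, row, col in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        exp = row * col / n
        chi2 += (obs - exp) ** 2 / exp
    return chi2


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pooled two-proportion z statistic."""
    p1, p2 = k1 / n1, k2 / n2
    p = (k1 + k2) / (n1 + n2)
    return (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))


def welch_t(xs: list[float], ys: list[float]) -> float:
    nx, ny = len(xs), len(ys)
    mx, my = sum(xs) / nx, sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    return (mx - my) / math.sqrt(vx / nx + vy / ny)
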