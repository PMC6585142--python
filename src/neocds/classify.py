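"""Threshold-based classification of newborn size status and danger signs.

This is the diagnostic core of the decision-support tool.  It maps a
validated :class:`~neocds.core.InfantCase` plus its derived measures onto a
:class:`ConditionProfile`: one tri-state result (positive / negative /
not-assessable) per condition, the national-guideline thresholds being:

* low birth weight: birth weight < 2500 g
* small infant: birth weight < 2500 g or foot length < 74 mm (optionally
  also gestational age < 37 weeks)
* very low weight: birth *or* current weight < 1500 g
* weight loss, small infant: 8-10 % moderate, > 10 % severe
* weight loss, non-small infant: 10-15 % moderate, > 15 % severe
* fast breathing: respiratory rate > 60 breaths/min
* fever: temperature > 38.0 degC; hypothermia: temperature < 35.5 degC
* feeding intolerance: any one of five adverse feeding observations
* breastfeeding problems: any one of five favourable statements answered "no"

Missing inputs propagate ``not_assessable`` rather than silently reading as
negative, so a skipped measurement can never launder into an all-clear.
Every threshold lives in :class:`ClassificationConfig`; none is hard-coded
at a call site.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from neocds.core import (
    BREASTFEEDING_ITEMS,
    DANGER_SIGN_ITEMS,
    FEEDING_INTOLERANCE_ITEMS,
    DerivedMeasures,
    InfantCase,
    TriState,
    derive_measures,
)

__all__ = [
    "TriResult",
    "WeightLossCategory",
    "CONDITIONS",
    "DEFAULT_DANGER_SIGN_SET",
    "ClassificationConfig",
    "ConditionProfile",
    "classify_size",
    "classify_weight_loss",
    "classify_vitals",
    "classify_feeding",
    "classify_case",
]


class TriResult(str, Enum):
    positive = "positive"
    negative = "negative"
    not_assessable = "na"


class WeightLossCategory(str, Enum):
    none = "none"
    moderate = "moderate"
    severe = "severe"


#: the full condition set of the diagnostic output, in reporting order
CONDITIONS = (
    "low_birth_weight",
    "small",
    "very_low_weight_lt1500",
    "severe_weight_loss",
    "moderate_weight_loss",
    "poor_movement",
    "convulsion_history",
    "poor_feeding",
    "severe_chest_indrawing",
    "fast_breathing",
    "umbilicus_red_or_pus",
    "skin_pustules",
    "jaundice_soles_or_body",
    "eye_infection",
    "fever",
    "hypothermia",
    "feeding_intolerance",
    "breastfeeding_problems",
)

#: conditions whose positivity triggers the "any danger sign" referral flag.
#: Size status (low_birth_weight, small) and moderate findings counsel rather
#: than refer on their own; they enter referral via the small-infant additions
#: in the management rules.
DEFAULT_DANGER_SIGN_SET = (
    "poor_movement",
    "convulsion_history",
    "poor_feeding",
    "severe_chest_indrawing",
    "fast_breathing",
    "umbilicus_red_or_pus",
    "skin_pustules",
    "jaundice_soles_or_body",
    "eye_infection",
    "fever",
    "hypothermia",
    "severe_weight_loss",
    "very_low_weight_lt1500",
    "feeding_intolerance",
)


class ClassificationConfig(BaseModel):
    """All guideline thresholds, with documented defaults.

    Weight-loss bands are closed intervals on percent *loss* (a positive
    number); severity is strict beyond the band's upper edge, so a loss of
    exactly 10 % in a small infant is moderate, not severe.
    """

    model_config = ConfigDict(validate_assignment=True)

    lbw_threshold_g: float = 2500.0
    foot_length_threshold_mm: float = 74.0
    very_low_weight_g: float = 1500.0
    preterm_weeks: float = 37.0
    small_definition: str = "weight_or_foot"  # or "weight_or_foot_or_preterm"
    small_moderate_loss_band: tuple[float, float] = (8.0, 10.0)
    small_severe_loss_gt: float = 10.0
    nonsmall_moderate_loss_band: tuple[float, float] = (10.0, 15.0)
    nonsmall_severe_loss_gt: float = 15.0
    fast_breathing_bpm: float = 60.0
    fever_C: float = 38.0
    hypothermia_C: float = 35.5
    #: when size is not assessable, which bands grade weight loss
    unknown_size_uses_small_bands: bool = False
    danger_sign_set: tuple[str, ...] = DEFAULT_DANGER_SIGN_SET

    @model_validator(mode="after")
    def _check(self) -> "ClassificationConfig":
        for name in (
            "lbw_threshold_g",
            "foot_length_threshold_mm",
            "very_low_weight_g",
            "preterm_weeks",
            "fast_breathing_bpm",
            "fever_C",
            "hypothermia_C",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for band, sev in (
            (self.small_moderate_loss_band, self.small_severe_loss_gt),
            (self.nonsmall_moderate_loss_band, self.nonsmall_severe_loss_gt),
        ):
            if not (0 < band[0] <= band[1] <= sev):
                raise ValueError("weight-loss band edges must be ordered")
        if self.small_definition not in ("weight_or_foot", "weight_or_foot_or_preterm"):
            raise ValueError("unknown small_definition")
        unknown = set(self.danger_sign_set) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions in danger_sign_set: {sorted(unknown)}")
        return self


class ConditionProfile(BaseModel):
    """The diagnostic output for one case: tri-state result per condition."""

    model_config = ConfigDict(validate_assignment=True)

    infant_id: Optional[str] = None
    conditions: dict[str, TriResult]
    preterm: TriResult = TriResult.not_assessable
    any_danger_sign: bool = False
    eligible: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ConditionProfile":
        if set(self.conditions) != set(CONDITIONS):
            missing = set(CONDITIONS) - set(self.conditions)
            extra = set(self.conditions) - set(CONDITIONS)
            raise ValueError(f"condition set mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        if (
            self.conditions["severe_weight_loss"] is TriResult.positive
            and self.conditions["moderate_weight_loss"] is TriResult.positive
        ):
            raise ValueError("severe and moderate weight loss are mutually exclusive")
        return self

    def __getitem__(self, condition: str) -> TriResult:
        return self.conditions[condition]

    def positives(self) -> list[str]:
        return [c for c in CONDITIONS if self.conditions[c] is TriResult.positive]


def _flag(value: Optional[bool]) -> TriResult:
    if value is None:
        return TriResult.not_assessable
    return TriResult.positive if value else TriResult.negative


def classify_size(
    case: InfantCase,
    derived: DerivedMeasures,
    config: ClassificationConfig | None = None,
) -> dict[str, TriResult]:
    """Size status: low birth weight, small, very-low-weight, preterm.

    A composite (small, very-low-weight) is positive as soon as any available
    criterion fires; it is negative when at least one criterion was available
    and none fired; only when every criterion is unavailable is it
    not-assessable.  In particular small is always resolvable when a birth
    weight is on record.
    """
    config = config or ClassificationConfig()
    bw = case.birth_weight_g
    cw = case.current_weight_g

    lbw = _flag(None if bw is None else bw < config.lbw_threshold_g)

    small_criteria: list[bool] = []
    if bw is not None:
        small_criteria.append(bw < config.lbw_threshold_g)
    if case.foot_length_mm is not None:
        small_criteria.append(case.foot_length_mm < config.foot_length_threshold_mm)
    if config.small_definition == "weight_or_foot_or_preterm" and derived.preterm is not None:
        small_criteria.append(derived.preterm)
    small = _flag(any(small_criteria) if small_criteria else None)

    weights = [w for w in (bw, cw) if w is not None]
    vlw = _flag(any(w < config.very_low_weight_g for w in weights) if weights else None)

    preterm = _flag(derived.preterm)
    return {
        "low_birth_weight": lbw,
        "small": small,
        "very_low_weight_lt1500": vlw,
        "preterm": preterm,
    }


def classify_weight_loss(
    percent: float,
    small: bool,
    config: ClassificationConfig | None = None,
) -> WeightLossCategory:
    """Grade percent weight change (negative = loss) against the size-specific
    bands.  Gains are never loss."""
    config = config or ClassificationConfig()
    loss = -percent
    if small:
        band, severe_gt = config.small_moderate_loss_band, config.small_severe_loss_gt
    else:
        band, severe_gt = config.nonsmall_moderate_loss_band, config.nonsmall_severe_loss_gt
    if loss > severe_gt:
        return WeightLossCategory.severe
    if band[0] <= loss <= band[1]:
        return WeightLossCategory.moderate
    return WeightLossCategory.none


def classify_vitals(
    temperature_C: Optional[float],
    respiratory_rate_bpm: Optional[int],
    config: ClassificationConfig | None = None,
) -> dict[str, TriResult]:
    """Fever (> 38.0 degC), hypothermia (< 35.5 degC), fast breathing
    (> 60 bpm); all strict inequalities; missing input -> not assessable."""
    config = config or ClassificationConfig()
    fever = _flag(None if temperature_C is None else temperature_C > config.fever_C)
    hypo = _flag(None if temperature_C is None else temperature_C < config.hypothermia_C)
    fast = _flag(
        None if respiratory_rate_bpm is None else respiratory_rate_bpm > config.fast_breathing_bpm
    )
    return {"fever": fever, "hypothermia": hypo, "fast_breathing": fast}


def _composite(adverse: list[bool | None]) -> TriResult:
    # positive on any adverse item; negative only when all items resolved
    # non-adverse; otherwise not assessable
    if any(a is True for a in adverse):
        return TriResult.positive
    if all(a is False for a in adverse):
        return TriResult.negative
    return TriResult.not_assessable


def classify_feeding(case: InfantCase) -> dict[str, TriResult]:
    """Feeding-intolerance and breastfeeding-problem composites plus the
    directly observed poor-feeding sign."""
    fi_adverse: list[bool | None] = [
        None if v is TriState.not_assessed else (v is TriState.present)
        for v in (case.feeding_intolerance_items[k] for k in FEEDING_INTOLERANCE_ITEMS)
    ]
    bf_adverse: list[bool | None] = [
        None if v is TriState.not_assessed else (v is TriState.absent)
        for v in (case.breastfeeding_items[k] for k in BREASTFEEDING_ITEMS)
    ]
    tri_map = {
        TriState.present: TriResult.positive,
        TriState.absent: TriResult.negative,
        TriState.not_assessed: TriResult.not_assessable,
    }
    return {
        "feeding_intolerance": _composite(fi_adverse),
        "breastfeeding_problems": _composite(bf_adverse),
        "poor_feeding": tri_map[case.signs["poor_feeding"]],
    }


def classify_case(
    case: InfantCase,
    config: ClassificationConfig | None = None,
    derived: DerivedMeasures | None = None,
) -> ConditionProfile:
    """Run the full diagnostic algorithm on one case.

    Deterministic and total: every condition gets exactly one of positive /
    negative / not-assessable.  ``any_danger_sign`` is the OR over the
    configured danger-sign subset (positives only; a not-assessable result
    does not trigger it).
    """
    config = config or ClassificationConfig()
    derived = derived or derive_measures(case)

    size = classify_size(case, derived, config)
    results: dict[str, TriResult] = {
        "low_birth_weight": size["low_birth_weight"],
        "small": size["small"],
        "very_low_weight_lt1500": size["very_low_weight_lt1500"],
    }

    if derived.weight_change_percent is None:
        results["severe_weight_loss"] = TriResult.not_assessable
        results["moderate_weight_loss"] = TriResult.not_assessable
    else:
        if size["small"] is TriResult.not_assessable:
            small_for_bands = config.unknown_size_uses_small_bands
        else:
            small_for_bands = size["small"] is TriResult.positive
        cat = classify_weight_loss(derived.weight_change_percent, small_for_bands, config)
        results["severe_weight_loss"] = _flag(cat is WeightLossCategory.severe)
        results["moderate_weight_loss"] = _flag(cat is WeightLossCategory.moderate)

    results.update(classify_vitals(derived.temperature_C, derived.respiratory_rate_bpm, config))

    feeding = classify_feeding(case)
    results["feeding_intolerance"] = feeding["feeding_intolerance"]
    results["breastfeeding_problems"] = feeding["breastfeeding_problems"]
    results["poor_feeding"] = feeding["poor_feeding"]

    tri_map = {
        TriState.present: TriResult.positive,
        TriState.absent: TriResult.negative,
        TriState.not_assessed: TriResult.not_assessable,
    }
    for sign in DANGER_SIGN_ITEMS:
        if sign == "poor_feeding":
            continue
        results[sign] = tri_map[case.signs[sign]]

    any_danger = any(results[c] is TriResult.positive for c in config.danger_sign_set)
    return ConditionProfile(
        infant_id=case.infant_id,
        conditions=results,
        preterm=size["preterm"],
        any_danger_sign=any_danger,
        eligible=derived.eligible,
    )
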