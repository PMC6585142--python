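"""Case data model, validation, and auto-calculated derived measures.

An :class:`InfantCase` holds the raw observations a frontline health worker
records for one newborn at one encounter: identifiers, birth and assessment
datetimes, the mother's last menstrual period (LMP) date, weights in grams,
foot length in millimetres, axillary temperature, a 60-second breath count,
and tri-state observations (present / absent / not assessed) for the direct
danger signs and the feeding checklists.  From these the package
auto-calculates the measures a decision-support app derives for the worker:
postnatal age in whole days, gestational age in weeks from LMP, percent
weight change since birth, and the temperature normalised to Celsius.

Tri-states are serialised as ``yes`` / ``no`` / ``na`` so that a paper form
with an unanswered checkbox is representable and distinguishable from an
explicit negative finding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date, datetime
from enum import Enum
from typing import Any, Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "TriState",
    "Sex",
    "TemperatureUnit",
    "InfantCase",
    "DerivedMeasures",
    "ValidationIssue",
    "CaseValidationError",
    "OrderingError",
    "validate_case",
    "derive_measures",
    "postnatal_age_days",
    "gestational_age_weeks",
    "weight_change_percent",
    "normalize_temperature",
    "DANGER_SIGN_ITEMS",
    "FEEDING_INTOLERANCE_ITEMS",
    "BREASTFEEDING_ITEMS",
    "read_cases_csv",
    "write_cases_csv",
    "read_cases_json",
    "write_cases_json",
    "ELIGIBILITY_MAX_AGE_DAYS",
]

#: postnatal-age eligibility cut-off: infants are in scope while < 28 days old
ELIGIBILITY_MAX_AGE_DAYS = 28

#: direct-observation danger signs (one tri-state each)
DANGER_SIGN_ITEMS = (
    "poor_movement",
    "convulsion_history",
    "poor_feeding",
    "severe_chest_indrawing",
    "umbilicus_red_or_pus",
    "skin_pustules",
    "jaundice_soles_or_body",
    "eye_infection",
)

#: feeding-intolerance checklist: any single "yes" makes the composite positive
FEEDING_INTOLERANCE_ITEMS = (
    "chokes_on_feeds",
    "turns_blue_or_pale_feeding",
    "frequent_vomiting",
    "distended_or_tender_abdomen",
    "bloody_stools",
)

#: breastfeeding checklist: these are *favourable* statements, so any single
#: "no" indicates a breastfeeding problem
BREASTFEEDING_ITEMS = (
    "wakes_easily_for_feeds",
    "feeds_10min_per_side",
    "sleeps_comfortably_between_feeds",
    "five_plus_wet_diapers",
    "mothers_breasts_softened",
)


class TriState(str, Enum):
    """Present / absent / not-assessed observation state."""

    present = "yes"
    absent = "no"
    not_assessed = "na"


class Sex(str, Enum):
    female = "female"
    male = "male"
    unrecorded = "unrecorded"


class TemperatureUnit(str, Enum):
    C = "C"
    F = "F"


class OrderingError(ValueError):
    """Raised when dated events are supplied out of chronological order."""


class CaseValidationError(ValueError):
    """Raised by :func:`validate_case` in strict mode; carries the issue list."""

    def __init__(self, issues: list["ValidationIssue"]):
        self.issues = issues
        super().__init__("; ".join(str(i) for i in issues))


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    rule: str  # "range" | "ordering" | "input"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.field}: {self.message}"


def _default_signs() -> dict[str, TriState]:
    return {k: TriState.not_assessed for k in DANGER_SIGN_ITEMS}


def _default_fi() -> dict[str, TriState]:
    return {k: TriState.not_assessed for k in FEEDING_INTOLERANCE_ITEMS}


def _default_bf() -> dict[str, TriState]:
    return {k: TriState.not_assessed for k in BREASTFEEDING_ITEMS}


class InfantCase(BaseModel):
    """Raw observations for one newborn at one assessment encounter."""

    model_config = ConfigDict(validate_assignment=True)

    infant_id: str
    sex: Sex = Sex.unrecorded
    birth_datetime: datetime
    assessment_datetime: datetime
    lmp_date: Optional[date] = None
    birth_weight_g: Optional[float] = None
    current_weight_g: Optional[float] = None
    foot_length_mm: Optional[float] = None
    temperature_value: Optional[float] = None
    temperature_unit: TemperatureUnit = TemperatureUnit.C
    breath_count_60s: Optional[int] = None
    signs: dict[str, TriState] = Field(default_factory=_default_signs)
    feeding_intolerance_items: dict[str, TriState] = Field(default_factory=_default_fi)
    breastfeeding_items: dict[str, TriState] = Field(default_factory=_default_bf)

    def sign(self, name: str) -> TriState:
        return self.signs[name]


class DerivedMeasures(BaseModel):
    """Auto-calculated quantities for one case.

    ``gestational_age_weeks`` is the exact day count divided by 7 (rounding to
    one decimal is a rendering concern); ``weight_change_percent`` is negative
    for loss.
    """

    postnatal_age_days: int
    eligible: bool
    gestational_age_weeks: Optional[float] = None
    preterm: Optional[bool] = None
    weight_change_percent: Optional[float] = None
    respiratory_rate_bpm: Optional[int] = None
    temperature_C: Optional[float] = None


# ---------------------------------------------------------------------------
# auto-calculations


def postnatal_age_days(birth: datetime, assessment: datetime) -> int:
    """Whole calendar days elapsed between birth and assessment (floor)."""
    if assessment < birth:
        raise OrderingError("assessment_datetime precedes birth_datetime")
    return int((assessment - birth).total_seconds() // 86400)


def gestational_age_weeks(lmp: date, birth: date) -> float:
    """Gestational age in weeks = (days from LMP to birth) / 7, unrounded."""
    if lmp > birth:
        raise OrderingError("lmp_date is after birth date")
    return (birth - lmp).days / 7.0


def weight_change_percent(birth_weight_g: float, current_weight_g: float) -> float:
    """Percent change from birth weight; negative denotes loss."""
    if birth_weight_g <= 0 or current_weight_g <= 0:
        raise ValueError("weights must be positive")
    return 100.0 * (current_weight_g - birth_weight_g) / birth_weight_g


def normalize_temperature(value: float, unit: TemperatureUnit | str) -> float:
    """Convert a recorded temperature to Celsius, rounded to 0.1 degC."""
    unit = TemperatureUnit(unit)
    if unit is TemperatureUnit.F:
        value = (value - 32.0) * 5.0 / 9.0
    return round(value, 1)


def derive_measures(case: InfantCase) -> DerivedMeasures:
    """Compute every derived measure available from the recorded fields.

    Preterm status (< 37.0 completed weeks, strict) is only defined when an
    LMP date was recorded.
    """
    age = postnatal_age_days(case.birth_datetime, case.assessment_datetime)
    ga = None
    preterm = None
    if case.lmp_date is not None:
        ga = gestational_age_weeks(case.lmp_date, case.birth_datetime.date())
        preterm = ga < 37.0
    wcp = None
    if case.birth_weight_g is not None and case.current_weight_g is not None:
        wcp = weight_change_percent(case.birth_weight_g, case.current_weight_g)
    temp_c = None
    if case.temperature_value is not None:
        temp_c = normalize_temperature(case.temperature_value, case.temperature_unit)
    return DerivedMeasures(
        postnatal_age_days=age,
        eligible=age < ELIGIBILITY_MAX_AGE_DAYS,
        gestational_age_weeks=ga,
        preterm=preterm,
        weight_change_percent=wcp,
        respiratory_rate_bpm=case.breath_count_60s,
        temperature_C=temp_c,
    )


# ---------------------------------------------------------------------------
# validation

_WEIGHT_RANGE_G = (200.0, 8000.0)  # exclusive low, inclusive high
_TEMP_RANGE_C = (25.0, 45.0)
_BREATH_MAX = 200


def validate_case(case: InfantCase, strict: bool = False) -> list[ValidationIssue]:
    """Check a parsed case against the data-entry constraints.

    Returns the list of violations (empty if the record is well formed).
    With ``strict=True`` a non-empty list raises :class:`CaseValidationError`
    instead, so pipelines can fail fast.
    """
    issues: list[ValidationIssue] = []
    if case.assessment_datetime < case.birth_datetime:
        issues.append(
            ValidationIssue(
                "assessment_datetime",
                "ordering",
                "assessment precedes birth",
            )
        )
    if case.lmp_date is not None and case.lmp_date > case.birth_datetime.date():
        issues.append(ValidationIssue("lmp_date", "ordering", "LMP after birth"))
    for field in ("birth_weight_g", "current_weight_g"):
        w = getattr(case, field)
        if w is not None and not (_WEIGHT_RANGE_G[0] < w <= _WEIGHT_RANGE_G[1]):
            issues.append(
                ValidationIssue(
                    field,
                    "range",
                    f"weight {w} g outside ({_WEIGHT_RANGE_G[0]:g}, {_WEIGHT_RANGE_G[1]:g}] g",
                )
            )
    if case.temperature_value is not None:
        try:
            t = normalize_temperature(case.temperature_value, case.temperature_unit)
        except ValueError:
            issues.append(ValidationIssue("temperature_unit", "input", "unknown unit"))
        else:
            if not (_TEMP_RANGE_C[0] <= t <= _TEMP_RANGE_C[1]):
                issues.append(
                    ValidationIssue(
                        "temperature_value",
                        "range",
                        f"{t} degC outside [{_TEMP_RANGE_C[0]:g}, {_TEMP_RANGE_C[1]:g}] degC",
                    )
                )
    if case.breath_count_60s is not None and not (0 <= case.breath_count_60s <= _BREATH_MAX):
        issues.append(
            ValidationIssue(
                "breath_count_60s",
                "range",
                f"breath count {case.breath_count_60s} outside [0, {_BREATH_MAX}]",
            )
        )
    if strict and issues:
        raise CaseValidationError(issues)
    return issues


# ---------------------------------------------------------------------------
# serialisation: CSV (one row per encounter) and JSON (one object per encounter)

_SCALAR_COLUMNS = [
    "infant_id",
    "sex",
    "birth_datetime",
    "assessment_datetime",
    "lmp_date",
    "birth_weight_g",
    "current_weight_g",
    "foot_length_mm",
    "temperature_value",
    "temperature_unit",
    "breath_count_60s",
]

CASE_COLUMNS = (
    _SCALAR_COLUMNS
    + list(DANGER_SIGN_ITEMS)
    + list(FEEDING_INTOLERANCE_ITEMS)
    + list(BREASTFEEDING_ITEMS)
)


def case_to_row(case: InfantCase) -> dict[str, Any]:
    row: dict[str, Any] = {
        "infant_id": case.infant_id,
        "sex": case.sex.value,
        "birth_datetime": case.birth_datetime.isoformat(),
        "assessment_datetime": case.assessment_datetime.isoformat(),
        "lmp_date": case.lmp_date.isoformat() if case.lmp_date else "",
        "birth_weight_g": case.birth_weight_g,
        "current_weight_g": case.current_weight_g,
        "foot_length_mm": case.foot_length_mm,
        "temperature_value": case.temperature_value,
        "temperature_unit": case.temperature_unit.value,
        "breath_count_60s": case.breath_count_60s,
    }
    for k, v in case.signs.items():
        row[k] = v.value
    for k, v in case.feeding_intolerance_items.items():
        row[k] = v.value
    for k, v in case.breastfeeding_items.items():
        row[k] = v.value
    return row


def _opt_float(v: Any) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _tri(v: Any) -> TriState:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return TriState.not_assessed
    return TriState(str(v))


def case_from_row(row: dict[str, Any]) -> InfantCase:
    bc = _opt_float(row.get("breath_count_60s"))
    lmp = row.get("lmp_date")
    lmp_date = None
    if lmp not in (None, "") and not (isinstance(lmp, float) and math.isnan(lmp)):
        lmp_date = date.fromisoformat(str(lmp))
    return InfantCase(
        infant_id=str(row["infant_id"]),
        sex=Sex(row.get("sex") or "unrecorded"),
        birth_datetime=datetime.fromisoformat(str(row["birth_datetime"])),
        assessment_datetime=datetime.fromisoformat(str(row["assessment_datetime"])),
        lmp_date=lmp_date,
        birth_weight_g=_opt_float(row.get("birth_weight_g")),
        current_weight_g=_opt_float(row.get("current_weight_g")),
        foot_length_mm=_opt_float(row.get("foot_length_mm")),
        temperature_value=_opt_float(row.get("temperature_value")),
        temperature_unit=TemperatureUnit(row.get("temperature_unit") or "C"),
        breath_count_60s=int(bc) if bc is not None else None,
        signs={k: _tri(row.get(k)) for k in DANGER_SIGN_ITEMS},
        feeding_intolerance_items={k: _tri(row.get(k)) for k in FEEDING_INTOLERANCE_ITEMS},
        breastfeeding_items={k: _tri(row.get(k)) for k in BREASTFEEDING_ITEMS},
    )


def cases_to_frame(cases: Iterable[InfantCase]) -> pd.DataFrame:
    return pd.DataFrame([case_to_row(c) for c in cases], columns=CASE_COLUMNS)


def write_cases_csv(cases: Iterable[InfantCase], path) -> None:
    cases_to_frame(cases).to_csv(path, index=False)


def read_cases_csv(path) -> list[InfantCase]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return [case_from_row(row) for row in df.to_dict(orient="records")]


def write_cases_json(cases: Iterable[InfantCase], path) -> None:
    with open(path, "w") as fh:
        json.dump([case_to_row(c) for c in cases], fh, indent=1)


def read_cases_json(path) -> list[InfantCase]:
    with open(path) as fh:
        return [case_from_row(obj) for obj in json.load(fh)]
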