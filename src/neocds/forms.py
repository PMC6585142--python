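"""Schema-driven assessment forms: ordered items, skip logic, constraints,
double entry, completeness auditing, and the findings summary.

The engine is the structural difference between the two assessment methods
under study.  Mobile-method records are *produced through* the engine, which
refuses to advance past an unanswered required item, enforces range
constraints and double entry, and auto-fills computed fields — so a
mobile record is complete by construction.  Paper-method records are
ingested as-is, with whatever the assessor happened to write down, and the
completeness audit (:func:`completeness_report`) measures the difference.

A reconstructive newborn-assessment schema covering every field the
classifier consumes ships as package data (``data/cncp_form.yaml``); the
engine itself is schema-generic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from importlib import resources
from typing import Any, Callable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from neocds.core import (
    BREASTFEEDING_ITEMS,
    DANGER_SIGN_ITEMS,
    FEEDING_INTOLERANCE_ITEMS,
    gestational_age_weeks,
    postnatal_age_days,
    weight_change_percent,
)
from neocds.classify import ConditionProfile, TriResult
from neocds.manage import ManagementPlan

__all__ = [
    "FormItem",
    "FormSchema",
    "FormSchemaError",
    "ResponseIssue",
    "AssessmentRecord",
    "CompletenessFlags",
    "next_item",
    "validate_response",
    "engine_fill",
    "completeness_report",
    "summary_report",
    "load_bundled_schema",
    "FULL_ASSESSMENT_SIGN_ITEMS",
]

#: items that footnote-level "all danger signs were assessed" completeness
#: requires to be resolved yes/no
FULL_ASSESSMENT_SIGN_ITEMS = (
    DANGER_SIGN_ITEMS + FEEDING_INTOLERANCE_ITEMS + BREASTFEEDING_ITEMS
)


class FormSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseIssue:
    item_id: str
    rule: str  # "range" | "double_entry" | "type" | "choice"
    message: str
    blocking: bool = True


@dataclass(frozen=True)
class FormItem:
    """One ordered form item.

    ``skip`` is a predicate over earlier answers (see :func:`eval_predicate`);
    when it evaluates true the item is passed over entirely.  ``soft_range``
    marks implausible-but-legal values: outside it the engine emits a
    non-blocking check-your-entry warning rather than a violation.
    """

    id: str
    prompt: str = ""
    answer_type: str = "text"  # text|integer|decimal|date|datetime|select
    choices: Optional[tuple[str, ...]] = None
    range: Optional[tuple[float, float]] = None
    soft_range: Optional[tuple[float, float]] = None
    required: bool = True
    double_entry: bool = False
    skip: Optional[dict] = None
    compute: Optional[str] = None  # name in the computed-field registry
    tags: tuple[str, ...] = ()


class FormSchema:
    def __init__(self, items: Sequence[FormItem]):
        ids = [it.id for it in items]
        if len(set(ids)) != len(ids):
            raise FormSchemaError("item ids must be unique")
        seen: set[str] = set()
        for it in items:
            if it.skip is not None:
                for ref in _predicate_refs(it.skip):
                    if ref not in seen:
                        raise FormSchemaError(
                            f"skip predicate of {it.id!r} references {ref!r} which is not earlier"
                        )
            seen.add(it.id)
        self.items: tuple[FormItem, ...] = tuple(items)
        self._by_id = {it.id: it for it in items}

    def __getitem__(self, item_id: str) -> FormItem:
        return self._by_id[item_id]

    def __iter__(self):
        return iter(self.items)

    def ids(self) -> list[str]:
        return [it.id for it in self.items]


def _predicate_refs(pred: dict) -> list[str]:
    if "item" in pred:
        return [pred["item"]]
    if "not" in pred:
        return _predicate_refs(pred["not"])
    for key in ("all", "any"):
        if key in pred:
            out: list[str] = []
            for sub in pred[key]:
                out.extend(_predicate_refs(sub))
            return out
    raise FormSchemaError(f"malformed predicate: {pred!r}")


_OPS: dict[str, Callable[[Any, Any], bool]] = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}


def eval_predicate(pred: dict, answers: Mapping[str, Any]) -> bool:
    """Evaluate a skip predicate; an unanswered referenced item reads as
    unknown, and unknown comparisons are false (the section is shown)."""
    if "not" in pred:
        return not eval_predicate(pred["not"], answers)
    if "all" in pred:
        return all(eval_predicate(p, answers) for p in pred["all"])
    if "any" in pred:
        return any(eval_predicate(p, answers) for p in pred["any"])
    value = answers.get(pred["item"])
    if value is None:
        return False
    return _OPS[pred["op"]](value, pred["value"])


def next_item(schema: FormSchema, answers: Mapping[str, Any]) -> Optional[str]:
    """First unanswered, non-skipped item id; ``None`` when the form is done."""
    unknown = set(answers) - set(schema.ids())
    if unknown:
        raise FormSchemaError(f"answers reference unknown items: {sorted(unknown)}")
    for it in schema:
        if it.id in answers and answers[it.id] is not None:
            continue
        if it.skip is not None and eval_predicate(it.skip, answers):
            continue
        return it.id
    return None


def validate_response(
    item: FormItem, value: Any, previous_entry: Any = None
) -> list[ResponseIssue]:
    """Check one response against the item's constraints.

    Returns all issues found; blocking issues (type, choice, range,
    double-entry mismatch) reject the response, non-blocking ones are
    check-your-entry warnings for implausible but legal values.
    """
    issues: list[ResponseIssue] = []
    if item.answer_type in ("integer", "decimal"):
        try:
            num = float(value)
        except (TypeError, ValueError):
            return [ResponseIssue(item.id, "type", f"expected a number, got {value!r}")]
        if item.answer_type == "integer" and float(value) != int(float(value)):
            issues.append(ResponseIssue(item.id, "type", "expected a whole number"))
        if item.range is not None and not (item.range[0] <= num <= item.range[1]):
            issues.append(
                ResponseIssue(
                    item.id,
                    "range",
                    f"{num:g} outside allowed range [{item.range[0]:g}, {item.range[1]:g}]",
                )
            )
        elif item.soft_range is not None and not (item.soft_range[0] <= num <= item.soft_range[1]):
            issues.append(
                ResponseIssue(
                    item.id,
                    "range",
                    f"{num:g} is unusual; please re-check",
                    blocking=False,
                )
            )
    elif item.answer_type == "select":
        if item.choices is not None and value not in item.choices:
            issues.append(
                ResponseIssue(item.id, "choice", f"{value!r} not one of {item.choices}")
            )
    if item.double_entry and previous_entry is not None and value != previous_entry:
        issues.append(
            ResponseIssue(
                item.id,
                "double_entry",
                f"entries disagree ({previous_entry!r} vs {value!r})",
            )
        )
    return issues


# ---------------------------------------------------------------------------
# computed fields

def _compute_postnatal_age(ans: Mapping[str, Any]) -> int:
    return postnatal_age_days(ans["birth_datetime"], ans["assessment_datetime"])


def _compute_ga(ans: Mapping[str, Any]) -> float:
    lmp = ans["lmp_date"]
    birth = ans["birth_datetime"]
    if isinstance(birth, datetime):
        birth = birth.date()
    if isinstance(lmp, str):
        lmp = date.fromisoformat(lmp)
    return round(gestational_age_weeks(lmp, birth), 1)


def _compute_weight_change(ans: Mapping[str, Any]) -> float:
    return round(weight_change_percent(ans["birth_weight_g"], ans["current_weight_g"]), 1)


def _compute_is_small(ans: Mapping[str, Any]) -> str:
    bw = ans.get("birth_weight_g")
    fl = ans.get("foot_length_mm")
    small = (bw is not None and bw < 2500.0) or (fl is not None and fl < 74.0)
    return "yes" if small else "no"


COMPUTED_FIELDS: dict[str, Callable[[Mapping[str, Any]], Any]] = {
    "postnatal_age_days": _compute_postnatal_age,
    "gestational_age_weeks": _compute_ga,
    "weight_change_percent": _compute_weight_change,
    "is_small": _compute_is_small,
}


def engine_fill(
    schema: FormSchema,
    source: Mapping[str, Any],
    enforce: bool = True,
) -> dict[str, Any]:
    """Drive the form like the mobile app: walk items in order, pulling each
    answer from ``source``, auto-filling computed fields, and refusing to
    advance when a required item has no acceptable answer.

    Skipped items never appear in the returned answers.  The unanswered-item
    count strictly decreases each step, so the walk terminates.
    """
    answers: dict[str, Any] = {}
    while True:
        item_id = next_item(schema, answers)
        if item_id is None:
            return answers
        item = schema[item_id]
        if item.compute is not None:
            answers[item_id] = COMPUTED_FIELDS[item.compute](answers)
            continue
        value = source.get(item_id)
        if value is None:
            if item.required and enforce:
                raise FormSchemaError(f"required item {item_id!r} has no answer")
            answers[item_id] = ""  # explicitly left blank (optional item)
            continue
        issues = [i for i in validate_response(item, value) if i.blocking]
        if issues and enforce:
            raise FormSchemaError(f"rejected answer for {item_id!r}: {issues[0].message}")
        answers[item_id] = value


# ---------------------------------------------------------------------------
# records and completeness


class CompletenessFlags(BaseModel):
    """One record's completeness audit.

    ``ga_calculated_if_lmp`` is ``None`` when no LMP was recorded — such
    records drop out of that row's denominator downstream.
    """

    full_assessment: bool
    any_recommendation: bool
    rr_recorded: bool
    temp_recorded: bool
    weight_recorded: bool
    weight_loss_calculated: bool
    ga_calculated_if_lmp: Optional[bool] = None
    postnatal_age_calculated: bool

    @model_validator(mode="after")
    def _check(self) -> "CompletenessFlags":
        if self.full_assessment and not (
            self.rr_recorded
            and self.temp_recorded
            and self.weight_recorded
            and self.any_recommendation
        ):
            raise ValueError(
                "full_assessment requires RR, temperature, weight and a recommendation"
            )
        return self


class AssessmentRecord(BaseModel):
    """One assessor's encounter: method, answers as recorded, and outputs."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    method: str  # "mobile" | "paper"
    chw_id: str
    infant_id: str
    answers: dict[str, Any] = Field(default_factory=dict)
    recommendations: list[str] = Field(default_factory=list)
    start_time: Optional[datetime] = None
    end_time: Optional[datetime] = None

    @model_validator(mode="after")
    def _check(self) -> "AssessmentRecord":
        if self.method not in ("mobile", "paper"):
            raise ValueError("method must be 'mobile' or 'paper'")
        if self.start_time and self.end_time and self.end_time < self.start_time:
            raise ValueError("end_time precedes start_time")
        return self

    def answered(self, item_id: str) -> bool:
        v = self.answers.get(item_id)
        return v is not None and v != "" and v != "na"

    @property
    def duration_minutes(self) -> Optional[float]:
        if self.start_time is None or self.end_time is None:
            return None
        return (self.end_time - self.start_time).total_seconds() / 60.0


def completeness_report(
    record: AssessmentRecord, lmp_recorded: Optional[bool] = None
) -> CompletenessFlags:
    """Audit one record against the completeness definitions: a full
    assessment has every danger-sign item resolved yes/no, a weight, a
    temperature, a respiratory rate, and at least one recommendation."""
    if lmp_recorded is None:
        lmp_recorded = record.answered("lmp_date")
    rr = record.answered("breath_count_60s")
    temp = record.answered("temperature_value")
    weight = record.answered("birth_weight_g") or record.answered("current_weight_g")
    rec = len(record.recommendations) > 0
    signs_done = all(record.answers.get(s) in ("yes", "no") for s in FULL_ASSESSMENT_SIGN_ITEMS)
    return CompletenessFlags(
        full_assessment=signs_done and rr and temp and weight and rec,
        any_recommendation=rec,
        rr_recorded=rr,
        temp_recorded=temp,
        weight_recorded=weight,
        weight_loss_calculated=record.answered("weight_change_percent"),
        ga_calculated_if_lmp=(record.answered("gestational_age_weeks") if lmp_recorded else None),
        postnatal_age_calculated=record.answered("postnatal_age_days"),
    )


# ---------------------------------------------------------------------------
# findings summary


def summary_report(case, profile: ConditionProfile, plan: ManagementPlan) -> str:
    """Deterministic text rendering of the summary-of-findings page."""
    lines = [f"ASSESSMENT SUMMARY — infant {case.infant_id}"]
    positives = profile.positives()
    if positives:
        lines.append("Conditions identified:")
        for c in positives:
            lines.append(f"  - {c.replace('_', ' ')}")
    else:
        lines.append("No danger signs identified.")
    unassessed = [c for c in profile.conditions if profile[c] is TriResult.not_assessable]
    if unassessed:
        lines.append("Not assessable: " + ", ".join(sorted(unassessed)))
    if profile["small"] is TriResult.positive:
        lines.append("Small baby: apply small-baby care (warmth, feeding support).")
    if plan.counseling:
        lines.append("Counseling:")
        for item in sorted(plan.counseling):
            lines.append(f"  - {item.replace('_', ' ')}")
    if plan.refer:
        lines.append(
            "REFER to facility now. Reasons: "
            + ", ".join(r.replace("_", " ") for r in plan.referral_reasons)
        )
    elif plan.follow_up_date is not None:
        lines.append(f"Follow-up visit: {plan.follow_up_date.isoformat()}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# bundled schema


def schema_from_dict(data: dict) -> FormSchema:
    items = []
    for raw in data["items"]:
        items.append(
            FormItem(
                id=raw["id"],
                prompt=raw.get("prompt", ""),
                answer_type=raw.get("answer_type", "text"),
                choices=tuple(raw["choices"]) if "choices" in raw else None,
                range=tuple(raw["range"]) if "range" in raw else None,
                soft_range=tuple(raw["soft_range"]) if "soft_range" in raw else None,
                required=raw.get("required", True),
                double_entry=raw.get("double_entry", False),
                skip=raw.get("skip"),
                compute=raw.get("compute"),
                tags=tuple(raw.get("tags", ())),
            )
        )
    return FormSchema(items)


def load_schema(path) -> FormSchema:
    with open(path) as fh:
        return schema_from_dict(yaml.safe_load(fh))


def load_bundled_schema() -> FormSchema:
    """The newborn-assessment form shipped with the package (reconstructive:
    it covers every field the classifier and the completeness audit use)."""
    text = resources.files("neocds").joinpath("data/cncp_form.yaml").read_text()
    return schema_from_dict(yaml.safe_load(text))
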