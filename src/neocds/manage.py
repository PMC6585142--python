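"""Case management: referral decision, counseling items, follow-up date.

Turns a :class:`~neocds.classify.ConditionProfile` into the summary-page
outputs a health worker acts on.  Referral follows the single-danger-sign
rule — any positive danger sign refers — plus lower small-infant thresholds
(a small infant with moderate weight loss or breastfeeding problems is also
referred).  Counseling maps conditions to advice items (kangaroo mother
care, cup feeding, increased feeding frequency, ...) and non-referred
infants get a scheduled follow-up visit, sooner when small or moderately
unwell.

The guideline source names the counseling items but not the full mapping, so
the mapping and follow-up offsets here are explicit package defaults in
:class:`ManagementConfig`, overridable from config without code change.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from neocds.classify import CONDITIONS, ConditionProfile, TriResult

__all__ = [
    "COUNSELING_ITEMS",
    "ManagementConfig",
    "ManagementPlan",
    "ManagementConfigError",
    "decide_referral",
    "counseling_items",
    "follow_up_date",
    "build_plan",
]

#: the advice vocabulary of the summary page
COUNSELING_ITEMS = (
    "kangaroo_mother_care",
    "cup_feeding",
    "increase_feeding_frequency",
    "thermal_care",
    "small_infant_breastfeeding_advice",
    "general_breastfeeding_support",
    "cord_care_advice",
)


class ManagementConfigError(ValueError):
    """A condition is missing from the referral rule table."""


def _default_referral_rules() -> dict[str, bool]:
    from neocds.classify import DEFAULT_DANGER_SIGN_SET

    return {c: c in DEFAULT_DANGER_SIGN_SET for c in CONDITIONS}


def _default_small_additions() -> list[list[str]]:
    # lower referral thresholds for small infants
    return [
        ["small", "moderate_weight_loss"],
        ["small", "breastfeeding_problems"],
    ]


def _default_counseling_rules() -> list[dict]:
    return [
        {"when_any": ["small", "hypothermia"], "items": ["kangaroo_mother_care", "thermal_care"]},
        {
            "when_all": ["small", "breastfeeding_problems"],
            "items": ["small_infant_breastfeeding_advice", "cup_feeding"],
        },
        {
            "when_any": ["moderate_weight_loss", "severe_weight_loss", "poor_feeding"],
            "items": ["increase_feeding_frequency"],
        },
        {"when_any": ["breastfeeding_problems"], "items": ["general_breastfeeding_support"]},
        {"when_any": ["umbilicus_red_or_pus"], "items": ["cord_care_advice"]},
    ]


class ManagementConfig(BaseModel):
    """Referral rule table, counseling mapping, and follow-up offsets."""

    model_config = ConfigDict(validate_assignment=True)

    referral_rules: dict[str, bool] = Field(default_factory=_default_referral_rules)
    small_referral_additions: list[list[str]] = Field(default_factory=_default_small_additions)
    counseling_rules: list[dict] = Field(default_factory=_default_counseling_rules)
    follow_up_days_small_or_moderate: int = 2
    follow_up_days_routine: int = 7

    @model_validator(mode="after")
    def _check(self) -> "ManagementConfig":
        missing = set(CONDITIONS) - set(self.referral_rules)
        if missing:
            raise ManagementConfigError(f"referral rule table missing conditions: {sorted(missing)}")
        for rule in self.counseling_rules:
            bad = set(rule.get("items", [])) - set(COUNSELING_ITEMS)
            if bad:
                raise ValueError(f"unknown counseling items: {sorted(bad)}")
        return self


class ManagementPlan(BaseModel):
    """Summary-page output: refer or follow up, with counseling advice."""

    infant_id: Optional[str] = None
    refer: bool
    referral_reasons: list[str] = Field(default_factory=list)
    counseling: set[str] = Field(default_factory=set)
    follow_up_date: Optional[date] = None

    @model_validator(mode="after")
    def _check(self) -> "ManagementPlan":
        if self.refer and not self.referral_reasons:
            raise ValueError("referral requires at least one reason")
        if self.refer and self.follow_up_date is not None:
            raise ValueError("referral supersedes scheduled follow-up")
        return self


def _positive(profile: ConditionProfile, condition: str) -> bool:
    return profile[condition] is TriResult.positive


def decide_referral(
    profile: ConditionProfile, config: ManagementConfig | None = None
) -> tuple[bool, list[str]]:
    """Apply the rule table: refer on any positive referring condition or any
    small-infant addition; reasons list every firing condition in profile
    order."""
    config = config or ManagementConfig()
    reasons: list[str] = []
    for condition in CONDITIONS:
        try:
            refers = config.referral_rules[condition]
        except KeyError as exc:  # pragma: no cover - blocked by config validation
            raise ManagementConfigError(f"no referral rule for {condition}") from exc
        if refers and _positive(profile, condition):
            reasons.append(condition)
    for conjunction in config.small_referral_additions:
        if all(_positive(profile, c) for c in conjunction):
            for c in conjunction:
                if c not in reasons:
                    reasons.append(c)
    reasons = sorted(reasons, key=CONDITIONS.index)
    return bool(reasons), reasons


def counseling_items(
    profile: ConditionProfile, config: ManagementConfig | None = None
) -> set[str]:
    """Union of advice items over all firing counseling rules."""
    config = config or ManagementConfig()
    items: set[str] = set()
    for rule in config.counseling_rules:
        fired = False
        if "when_all" in rule:
            fired = all(_positive(profile, c) for c in rule["when_all"])
        elif "when_any" in rule:
            fired = any(_positive(profile, c) for c in rule["when_any"])
        if fired:
            items.update(rule["items"])
    return items


def follow_up_date(
    profile: ConditionProfile,
    assessment_date: date,
    config: ManagementConfig | None = None,
    refer: Optional[bool] = None,
) -> Optional[date]:
    """Schedule the next visit: none when referred; sooner (+2 d default)
    when small or moderately unwell; routine (+7 d default) otherwise."""
    config = config or ManagementConfig()
    if refer is None:
        refer, _ = decide_referral(profile, config)
    if refer:
        return None
    if _positive(profile, "small") or _positive(profile, "moderate_weight_loss"):
        return assessment_date + timedelta(days=config.follow_up_days_small_or_moderate)
    return assessment_date + timedelta(days=config.follow_up_days_routine)


def build_plan(
    profile: ConditionProfile,
    assessment_date: date,
    config: ManagementConfig | None = None,
) -> ManagementPlan:
    """Compose referral, counseling, and follow-up into one plan."""
    config = config or ManagementConfig()
    refer, reasons = decide_referral(profile, config)
    return ManagementPlan(
        infant_id=profile.infant_id,
        refer=refer,
        referral_reasons=reasons,
        counseling=counseling_items(profile, config),
        follow_up_date=follow_up_date(profile, assessment_date, config, refer=refer),
    )
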