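"""Synthetic study generator: infant cohorts and simulated assessor error.

Two layers:

* :func:`generate_cohort` draws a cohort of newborn cases whose *raw
  measurements are consistent with their gold labels by construction*.  For
  each threshold-based condition the binary gold label is drawn from its
  prevalence and the underlying measurement is then sampled from the matching
  side of the guideline threshold (with a safety margin so unit conversion
  and gram rounding cannot flip a label); observational signs are set
  directly.  Every generated case satisfies ``classify_case(case) == gold``
  exactly, and this is re-checked for every infant at generation time.

* :func:`simulate_assessments` replays the crossover design: each assessor
  (CHW) starts with the method given by the parity of her ID number, works
  in blocks of six assessments, then switches.  Per condition the simulated
  call matches gold with a probability given by the error model's accuracy,
  shifted on the log-odds scale by a per-CHW random effect.  Paper-method
  records additionally lose recorded fields to missingness; mobile-method
  records are produced through the form engine and are therefore complete by
  construction.

Default prevalences, age/gestation distributions and error-model accuracies
are calibrated to the expert-classification column and the per-method
correctness proportions of the reference field study (shipped as a labeled
config, ``data/error_model.yaml``).

Weight-loss severity is a three-way category (none / moderate / severe), so
the two weight-loss conditions are simulated jointly as a categorical call
whose marginals match the configured per-condition accuracies (clipped to
the feasible simplex) — independent flips could assert severe and moderate
loss simultaneously, which no coherent assessor can.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from neocds.classify import (
    CONDITIONS,
    ClassificationConfig,
    ConditionProfile,
    TriResult,
    classify_case,
)
from neocds.core import (
    BREASTFEEDING_ITEMS,
    DANGER_SIGN_ITEMS,
    FEEDING_INTOLERANCE_ITEMS,
    InfantCase,
    Sex,
    TemperatureUnit,
    TriState,
)
from neocds.evaluate import LabeledAssessment, label_assessment
from neocds.forms import AssessmentRecord, engine_fill, load_bundled_schema
from neocds.manage import ManagementConfig, build_plan

__all__ = [
    "CohortSpec",
    "ErrorModel",
    "CohortSpecError",
    "DesignError",
    "generate_cohort",
    "simulate_assessments",
    "implied_correct_proportions",
    "load_default_error_model",
    "DEFAULT_PREVALENCE",
]

#: default condition prevalences: the expert-classification column of the
#: reference study's paper-method cohort
DEFAULT_PREVALENCE: dict[str, float] = {
    "low_birth_weight": 0.488,
    "small": 0.488,
    "very_low_weight_lt1500": 0.071,
    "severe_weight_loss": 0.250,
    "moderate_weight_loss": 0.214,
    "poor_movement": 0.036,
    "convulsion_history": 0.226,
    "poor_feeding": 0.619,
    "severe_chest_indrawing": 0.036,
    "fast_breathing": 0.214,
    "umbilicus_red_or_pus": 0.155,
    "skin_pustules": 0.0,
    "jaundice_soles_or_body": 0.107,
    "eye_infection": 0.0,
    "fever": 0.155,
    "hypothermia": 0.060,
    "feeding_intolerance": 0.083,
    "breastfeeding_problems": 0.381,
}


class CohortSpecError(ValueError):
    pass


class DesignError(ValueError):
    pass


class CohortSpec(BaseModel):
    """Study-condition parameters of the synthetic cohort."""

    model_config = ConfigDict(validate_assignment=True)

    n_infants: int = 100
    prevalence: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    postnatal_age_mean: float = 6.5
    postnatal_age_sd: float = 6.7
    postnatal_age_range: tuple[int, int] = (0, 27)
    gestational_age_mean_weeks: float = 40.1
    gestational_age_sd_weeks: float = 3.2
    p_female: float = 0.31
    p_lmp_recorded: float = 0.33
    p_fahrenheit: float = 0.10
    study_date: date = date(2017, 3, 20)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n_infants < 1:
            raise CohortSpecError("n_infants must be >= 1")
        missing = set(CONDITIONS) - set(self.prevalence)
        if missing:
            raise CohortSpecError(f"prevalence missing for: {sorted(missing)}")
        for k, v in self.prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"prevalence[{k}] = {v} outside [0, 1]")
        p = self.prevalence
        if p["severe_weight_loss"] + p["moderate_weight_loss"] > 1.0:
            raise CohortSpecError("weight-loss category prevalences sum past 1")
        if p["fever"] + p["hypothermia"] > 1.0:
            raise CohortSpecError("fever + hypothermia prevalences sum past 1")
        if p["very_low_weight_lt1500"] > p["low_birth_weight"] and p["low_birth_weight"] > 0:
            raise CohortSpecError("very-low-weight prevalence exceeds low-birth-weight prevalence")
        if p["small"] < p["low_birth_weight"]:
            raise CohortSpecError("small prevalence cannot be below low-birth-weight prevalence")
        return self


def _load_yaml_resource(name: str) -> dict:
    text = resources.files("neocds").joinpath(f"data/{name}").read_text()
    return yaml.safe_load(text)


def _default_accuracy() -> dict[str, dict[str, float]]:
    return _load_yaml_resource("error_model.yaml")["accuracy"]


def _default_missingness() -> dict[str, float]:
    return _load_yaml_resource("error_model.yaml")["missingness"]


class ErrorModel(BaseModel):
    """Per-condition, per-method assessor accuracy plus the design knobs.

    ``sensitivity`` / ``specificity`` may differ; the shipped calibration
    sets them equal (the reference tables publish only overall correctness).
    ``chw_sd`` is the SD of a per-assessor normal random effect on the
    log-odds of a correct call.
    """

    model_config = ConfigDict(validate_assignment=True)

    sensitivity: dict[str, dict[str, float]] = Field(default_factory=_default_accuracy)
    specificity: dict[str, dict[str, float]] = Field(default_factory=_default_accuracy)
    chw_sd: float = 0.3
    missingness: dict[str, float] = Field(default_factory=_default_missingness)
    not_assessed_prob: float = 0.0
    n_chws: int = 12
    block_size: int = 6
    time_mean_mobile: float = 17.5
    time_sd_mobile: float = 10.8
    time_mean_paper: float = 23.6
    time_sd_paper: float = 11.6

    @model_validator(mode="after")
    def _check(self) -> "ErrorModel":
        for table in (self.sensitivity, self.specificity):
            for cond, per_method in table.items():
                for method, v in per_method.items():
                    if not 0.0 <= v <= 1.0:
                        raise ValueError(f"accuracy[{cond}][{method}] = {v} outside [0, 1]")
        for k, v in self.missingness.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missingness[{k}] = {v} outside [0, 1]")
        if self.n_chws < 1 or self.block_size < 1:
            raise ValueError("n_chws and block_size must be positive")
        return self

    def accuracy(self, condition: str, method: str, gold_positive: bool) -> float:
        table = self.sensitivity if gold_positive else self.specificity
        return table[condition][method]


def load_default_error_model(**overrides) -> ErrorModel:
    raw = _load_yaml_resource("error_model.yaml")
    kwargs = dict(
        sensitivity=raw["accuracy"],
        specificity=raw["accuracy"],
        chw_sd=raw["chw_sd"],
        missingness=raw["missingness"],
        not_assessed_prob=raw["not_assessed_prob"],
        n_chws=raw["n_chws"],
        block_size=raw["block_size"],
        time_mean_mobile=raw["time_mean_mobile"],
        time_sd_mobile=raw["time_sd_mobile"],
        time_mean_paper=raw["time_mean_paper"],
        time_sd_paper=raw["time_sd_paper"],
    )
    kwargs.update(overrides)
    return ErrorModel(**kwargs)


# ---------------------------------------------------------------------------
# cohort generation

_MAX_TRIES = 200


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated-normal rejection failed")  # pragma: no cover


def _sample_one(
    rng: np.random.Generator, spec: CohortSpec, config: ClassificationConfig, idx: int
) -> tuple[InfantCase, ConditionProfile]:
    p = spec.prevalence
    for _ in range(_MAX_TRIES):
        intended: dict[str, bool] = {}

        # --- size labels
        lbw = rng.random() < p["low_birth_weight"]
        if lbw:
            foot_short = rng.random() < 0.7  # short feet common in LBW; label-neutral
        else:
            p_rest = 1.0 - p["low_birth_weight"]
            p_foot_only = (p["small"] - p["low_birth_weight"]) / p_rest if p_rest > 0 else 0.0
            foot_short = rng.random() < p_foot_only
        small = lbw or foot_short
        if lbw and p["low_birth_weight"] > 0:
            vlw = rng.random() < p["very_low_weight_lt1500"] / p["low_birth_weight"]
        else:
            vlw = False
        intended["low_birth_weight"] = lbw
        intended["small"] = small
        intended["very_low_weight_lt1500"] = vlw

        # --- weight-loss category and weights (gram-rounded, with margins so
        # rounding cannot cross a band edge)
        u = rng.random()
        if u < p["severe_weight_loss"]:
            wl = "severe"
        elif u < p["severe_weight_loss"] + p["moderate_weight_loss"]:
            wl = "moderate"
        else:
            wl = "none"
        intended["severe_weight_loss"] = wl == "severe"
        intended["moderate_weight_loss"] = wl == "moderate"

        if vlw:
            birth_w = float(rng.integers(1000, 1496))
        elif lbw:
            birth_w = float(rng.integers(1800, 2496))
        else:
            birth_w = float(rng.integers(2550, 4201))
        if small:
            windows = {"severe": (10.3, 16.0), "moderate": (8.2, 9.8), "none": (-7.5, 5.0)}
        else:
            windows = {"severe": (15.3, 18.0), "moderate": (10.3, 14.7), "none": (-9.5, 5.0)}
        lo, hi = windows[wl]
        loss_pct = rng.uniform(lo, hi)
        current_w = float(round(birth_w * (1.0 - loss_pct / 100.0)))

        # --- vitals
        u = rng.random()
        if u < p["fever"]:
            temp_c, fever, hypo = rng.uniform(38.2, 40.0), True, False
        elif u < p["fever"] + p["hypothermia"]:
            temp_c, fever, hypo = rng.uniform(33.0, 35.3), False, True
        else:
            temp_c, fever, hypo = rng.uniform(36.0, 37.8), False, False
        intended["fever"], intended["hypothermia"] = fever, hypo
        if rng.random() < spec.p_fahrenheit:
            temp_value = round(temp_c * 9.0 / 5.0 + 32.0, 1)
            temp_unit = TemperatureUnit.F
        else:
            temp_value = round(temp_c, 1)
            temp_unit = TemperatureUnit.C

        fast = rng.random() < p["fast_breathing"]
        breath = int(rng.integers(61, 91)) if fast else int(rng.integers(30, 61))
        intended["fast_breathing"] = fast

        # --- direct signs
        signs: dict[str, TriState] = {}
        for sign in DANGER_SIGN_ITEMS:
            pos = rng.random() < p[sign]
            signs[sign] = TriState.present if pos else TriState.absent
            intended[sign] = pos

        # --- feeding composites
        fi_pos = rng.random() < p["feeding_intolerance"]
        fi_items = {k: TriState.absent for k in FEEDING_INTOLERANCE_ITEMS}
        if fi_pos:
            n_hit = int(rng.integers(1, 3))
            for k in rng.choice(FEEDING_INTOLERANCE_ITEMS, size=n_hit, replace=False):
                fi_items[str(k)] = TriState.present
        intended["feeding_intolerance"] = fi_pos

        bf_pos = rng.random() < p["breastfeeding_problems"]
        bf_items = {k: TriState.present for k in BREASTFEEDING_ITEMS}
        if bf_pos:
            n_hit = int(rng.integers(1, 3))
            for k in rng.choice(BREASTFEEDING_ITEMS, size=n_hit, replace=False):
                bf_items[str(k)] = TriState.absent
        intended["breastfeeding_problems"] = bf_pos

        # --- timing and gestation
        age_days = _trunc_normal(
            rng,
            spec.postnatal_age_mean,
            spec.postnatal_age_sd,
            spec.postnatal_age_range[0],
            spec.postnatal_age_range[1] + 0.999,
        )
        assess_dt = datetime.combine(spec.study_date, datetime.min.time()) + timedelta(
            hours=8, minutes=int(rng.integers(0, 540))
        )
        birth_dt = assess_dt - timedelta(days=int(age_days), hours=float(rng.uniform(0, 20)))
        if rng.random() < spec.p_lmp_recorded:
            ga_weeks = _trunc_normal(
                rng, spec.gestational_age_mean_weeks, spec.gestational_age_sd_weeks, 26.0, 44.0
            )
            lmp = birth_dt.date() - timedelta(days=int(round(ga_weeks * 7)))
        else:
            lmp = None

        foot_mm = round(float(rng.uniform(60.0, 73.4)) if foot_short else float(rng.uniform(74.5, 90.0)), 1)

        case = InfantCase(
            infant_id=f"I{idx:05d}",
            sex=Sex.female if rng.random() < spec.p_female else Sex.male,
            birth_datetime=birth_dt,
            assessment_datetime=assess_dt,
            lmp_date=lmp,
            birth_weight_g=birth_w,
            current_weight_g=current_w,
            foot_length_mm=foot_mm,
            temperature_value=temp_value,
            temperature_unit=temp_unit,
            breath_count_60s=breath,
            signs=signs,
            feeding_intolerance_items=fi_items,
            breastfeeding_items=bf_items,
        )
        profile = classify_case(case, config)
        ok = all(
            (profile[c] is TriResult.positive) == intended[c]
            and profile[c] is not TriResult.not_assessable
            for c in CONDITIONS
        )
        if ok:
            return case, profile
    raise RuntimeError("could not generate a label-consistent case")  # pragma: no cover


def generate_cohort(
    spec: CohortSpec,
    seed: Optional[int] = None,
    config: ClassificationConfig | None = None,
) -> tuple[list[InfantCase], list[ConditionProfile]]:
    """Generate ``spec.n_infants`` cases with gold profiles satisfying
    ``classify_case(case) == gold`` exactly (re-verified per infant)."""
    config = config or ClassificationConfig()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed if seed is not None else 0).spawn(3)[0])
    cases, golds = [], []
    for i in range(spec.n_infants):
        case, gold = _sample_one(rng, spec, config, i)
        cases.append(case)
        golds.append(gold)
    return cases, golds


# ---------------------------------------------------------------------------
# assessment simulation

_TRI_FROM_BOOL = {True: TriResult.positive, False: TriResult.negative}


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _shift(p: float, u: float) -> float:
    return _expit(_logit(p) + u)


def _weight_loss_call(
    rng: np.random.Generator, gold_cat: str, a_sev: float, a_mod: float
) -> str:
    """Draw the assessor's three-way weight-loss category so that the severe
    and moderate per-condition accuracies hold marginally (clipped to the
    feasible simplex)."""
    if gold_cat == "severe":
        p_sev = a_sev
        p_mod = min(1.0 - a_mod, 1.0 - p_sev)
    elif gold_cat == "moderate":
        p_mod = a_mod
        p_sev = min(1.0 - a_sev, 1.0 - p_mod)
    else:
        p_sev = 1.0 - a_sev
        p_mod = min(1.0 - a_mod, 1.0 - p_sev)
    u = rng.random()
    if u < p_sev:
        return "severe"
    if u < p_sev + p_mod:
        return "moderate"
    return "none"


def _simulate_profile(
    rng: np.random.Generator,
    gold: ConditionProfile,
    model: ErrorModel,
    method: str,
    u_chw: float,
) -> ConditionProfile:
    calls: dict[str, TriResult] = {}

    gold_sev = gold["severe_weight_loss"]
    if gold_sev is TriResult.not_assessable:
        calls["severe_weight_loss"] = TriResult.not_assessable
        calls["moderate_weight_loss"] = TriResult.not_assessable
    else:
        if gold_sev is TriResult.positive:
            gold_cat = "severe"
        elif gold["moderate_weight_loss"] is TriResult.positive:
            gold_cat = "moderate"
        else:
            gold_cat = "none"
        a_sev = _shift(
            model.accuracy("severe_weight_loss", method, gold_cat == "severe"), u_chw
        )
        a_mod = _shift(
            model.accuracy("moderate_weight_loss", method, gold_cat == "moderate"), u_chw
        )
        call_cat = _weight_loss_call(rng, gold_cat, a_sev, a_mod)
        calls["severe_weight_loss"] = _TRI_FROM_BOOL[call_cat == "severe"]
        calls["moderate_weight_loss"] = _TRI_FROM_BOOL[call_cat == "moderate"]

    for cond in CONDITIONS:
        if cond in ("severe_weight_loss", "moderate_weight_loss"):
            continue
        g = gold[cond]
        if g is TriResult.not_assessable:
            calls[cond] = TriResult.not_assessable
            continue
        gold_pos = g is TriResult.positive
        acc = _shift(model.accuracy(cond, method, gold_pos), u_chw)
        correct = rng.random() < acc
        calls[cond] = _TRI_FROM_BOOL[gold_pos if correct else not gold_pos]

    if method == "paper" and model.not_assessed_prob > 0:
        for cond in CONDITIONS:
            if rng.random() < model.not_assessed_prob:
                calls[cond] = TriResult.not_assessable

    # mutual exclusivity could only be violated by the NA pass; degrade safely
    if (
        calls["severe_weight_loss"] is TriResult.positive
        and calls["moderate_weight_loss"] is TriResult.positive
    ):  # pragma: no cover - unreachable by construction
        calls["moderate_weight_loss"] = TriResult.negative

    from neocds.classify import ClassificationConfig as _CC

    danger = any(calls[c] is TriResult.positive for c in _CC().danger_sign_set)
    return ConditionProfile(
        infant_id=gold.infant_id,
        conditions=calls,
        preterm=gold.preterm,
        any_danger_sign=danger,
        eligible=gold.eligible,
    )


def _case_answers(case: InfantCase, perceived: ConditionProfile) -> dict:
    """Source answers for the form engine: measurements transcribed from the
    case, sign answers reflecting the assessor's perceived calls."""
    ans = {
        "infant_id": case.infant_id,
        "sex": case.sex.value,
        "birth_datetime": case.birth_datetime,
        "assessment_datetime": case.assessment_datetime,
        "lmp_known": "yes" if case.lmp_date is not None else "no",
        "lmp_date": case.lmp_date,
        "birth_weight_g": case.birth_weight_g,
        "current_weight_g": case.current_weight_g,
        "foot_length_mm": case.foot_length_mm,
        "temperature_unit": case.temperature_unit.value,
        "temperature_value": case.temperature_value,
        "breath_count_60s": case.breath_count_60s,
        "kmc_counseled": "yes",
        "cup_feeding_counseled": "yes",
    }
    for sign in DANGER_SIGN_ITEMS:
        ans[sign] = "yes" if perceived[sign] is TriResult.positive else "no"
    for item in FEEDING_INTOLERANCE_ITEMS:
        ans[item] = case.feeding_intolerance_items[item].value
    for item in BREASTFEEDING_ITEMS:
        ans[item] = case.breastfeeding_items[item].value
    return ans


def _recommendations(perceived: ConditionProfile, assess_date: date) -> list[str]:
    plan = build_plan(perceived, assess_date, ManagementConfig())
    recs = []
    if plan.refer:
        recs.append("refer to facility: " + ", ".join(plan.referral_reasons))
    for item in sorted(plan.counseling):
        recs.append("counsel: " + item)
    if plan.follow_up_date is not None:
        recs.append("follow-up on " + plan.follow_up_date.isoformat())
    return recs


def simulate_assessments(
    cases: Sequence[InfantCase],
    gold: Sequence[ConditionProfile],
    model: ErrorModel | None = None,
    seed: Optional[int] = None,
    assessments_per_infant: int = 2,
    n_assessments: Optional[int] = None,
) -> tuple[list[AssessmentRecord], list[LabeledAssessment], list[ConditionProfile]]:
    """Simulate the crossover study on a generated cohort.

    Returns the assessment records (with method-dependent missingness), the
    per-condition labeled calls, and the simulated assessor profiles (one per
    record, aligned).
    """
    model = model or load_default_error_model()
    if len(cases) != len(gold):
        raise DesignError("cases and gold profiles differ in length")
    max_assessments = len(cases) * assessments_per_infant
    if n_assessments is None:
        n_assessments = max_assessments
    if n_assessments > max_assessments:
        raise DesignError(
            f"requested {n_assessments} assessments but the cohort supports {max_assessments}"
        )

    ss = np.random.SeedSequence(seed if seed is not None else 0).spawn(3)
    rng_error = np.random.default_rng(ss[1])
    rng_missing = np.random.default_rng(ss[2])

    schema = load_bundled_schema()
    chw_numbers = list(range(1, model.n_chws + 1))
    chw_effects = {n: float(rng_error.normal(0.0, model.chw_sd)) for n in chw_numbers}

    tasks = [i for i in range(len(cases)) for _ in range(assessments_per_infant)]
    rng_error.shuffle(tasks)
    tasks = tasks[:n_assessments]

    records: list[AssessmentRecord] = []
    labeled: list[LabeledAssessment] = []
    profiles: list[ConditionProfile] = []
    per_chw_count = {n: 0 for n in chw_numbers}

    for t, infant_idx in enumerate(tasks):
        chw_no = chw_numbers[t % len(chw_numbers)]
        chw_id = f"CHW{chw_no:02d}"
        k = per_chw_count[chw_no]
        per_chw_count[chw_no] += 1
        # even ID numbers start with the mobile method, odd with paper;
        # everyone switches after each block
        first = "mobile" if chw_no % 2 == 0 else "paper"
        other = "paper" if first == "mobile" else "mobile"
        method = first if (k // model.block_size) % 2 == 0 else other

        case, gold_profile = cases[infant_idx], gold[infant_idx]
        perceived = _simulate_profile(
            rng_error, gold_profile, model, method, chw_effects[chw_no]
        )
        answers_src = _case_answers(case, perceived)

        if method == "mobile":
            answers = engine_fill(schema, answers_src)
            recs = _recommendations(perceived, case.assessment_datetime.date())
            duration = max(3.0, rng_error.normal(model.time_mean_mobile, model.time_sd_mobile))
        else:
            answers = dict(answers_src)
            answers.pop("lmp_known", None)
            if answers.get("lmp_date") is None:
                answers.pop("lmp_date", None)
            m = model.missingness
            if rng_missing.random() < m.get("weight", 0.0):
                answers.pop("birth_weight_g", None)
                answers.pop("current_weight_g", None)
            else:
                answers["weight_change_percent"] = (
                    round(
                        100.0
                        * (case.current_weight_g - case.birth_weight_g)
                        / case.birth_weight_g,
                        1,
                    )
                    if rng_missing.random() >= m.get("weight_change_percent", 0.0)
                    else None
                )
                if answers.get("weight_change_percent") is None:
                    answers.pop("weight_change_percent", None)
            if rng_missing.random() < m.get("breath_count_60s", 0.0):
                answers.pop("breath_count_60s", None)
            if rng_missing.random() < m.get("temperature_value", 0.0):
                answers.pop("temperature_value", None)
                answers.pop("temperature_unit", None)
            if case.lmp_date is not None and rng_missing.random() >= m.get(
                "gestational_age_weeks", 0.0
            ):
                answers["gestational_age_weeks"] = round(
                    (case.birth_datetime.date() - case.lmp_date).days / 7.0, 1
                )
            if rng_missing.random() >= m.get("postnatal_age_days", 0.0):
                answers["postnatal_age_days"] = int(
                    (case.assessment_datetime - case.birth_datetime).total_seconds() // 86400
                )
            p_sign = m.get("sign", 0.0)
            for item in (
                DANGER_SIGN_ITEMS + FEEDING_INTOLERANCE_ITEMS + BREASTFEEDING_ITEMS
            ):
                if rng_missing.random() < p_sign:
                    answers.pop(item, None)
            answers.pop("kmc_counseled", None)
            answers.pop("cup_feeding_counseled", None)
            if rng_missing.random() < m.get("recommendation", 0.0):
                recs = []
            else:
                recs = _recommendations(perceived, case.assessment_datetime.date())
            duration = max(3.0, rng_error.normal(model.time_mean_paper, model.time_sd_paper))

        start = case.assessment_datetime
        record = AssessmentRecord(
            method=method,
            chw_id=chw_id,
            infant_id=case.infant_id,
            answers={k: v for k, v in answers.items() if v is not None},
            recommendations=recs,
            start_time=start,
            end_time=start + timedelta(minutes=duration),
        )
        records.append(record)
        profiles.append(perceived)
        labeled.extend(label_assessment(chw_id, case.infant_id, method, perceived, gold_profile))

    return records, labeled, profiles


# ---------------------------------------------------------------------------
# implied operating characteristics (for parameter-recovery checks)


def implied_correct_proportions(
    model: ErrorModel,
    gold: Sequence[ConditionProfile],
    method: str,
    n_quad: int = 31,
) -> dict[str, float]:
    """The correct-call proportion the error model implies for each condition
    on a given gold cohort, integrating the per-CHW random effect numerically
    (Gauss-Hermite) and applying the same weight-loss simplex clipping the
    simulator uses."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    u_vals = math.sqrt(2.0) * model.chw_sd * nodes
    w = weights / math.sqrt(math.pi)

    out: dict[str, float] = {}
    n = len(gold)
    for cond in CONDITIONS:
        total = 0.0
        for g in gold:
            if g[cond] is TriResult.not_assessable:
                continue
            if cond in ("severe_weight_loss", "moderate_weight_loss"):
                if g["severe_weight_loss"] is TriResult.positive:
                    gold_cat = "severe"
                elif g["moderate_weight_loss"] is TriResult.positive:
                    gold_cat = "moderate"
                else:
                    gold_cat = "none"
                acc_u = 0.0
                for ui, wi in zip(u_vals, w):
                    a_sev = _shift(
                        model.accuracy("severe_weight_loss", method, gold_cat == "severe"), ui
                    )
                    a_mod = _shift(
                        model.accuracy("moderate_weight_loss", method, gold_cat == "moderate"), ui
                    )
                    # mirror the simulator's clipped categorical call:
                    #   gold severe:   p_sev = a_sev, p_mod = min(1-a_mod, 1-a_sev)
                    #   gold moderate: p_mod = a_mod, p_sev = min(1-a_sev, 1-a_mod)
                    #   gold none:     p_sev = 1-a_sev, p_mod = min(1-a_mod, a_sev)
                    if gold_cat == "severe":
                        acc = a_sev if cond == "severe_weight_loss" else max(a_mod, a_sev)
                    elif gold_cat == "moderate":
                        acc = max(a_sev, a_mod) if cond == "severe_weight_loss" else a_mod
                    else:
                        acc = a_sev if cond == "severe_weight_loss" else max(a_mod, 1.0 - a_sev)
                    acc_u += wi * acc
            else:
                gold_pos = g[cond] is TriResult.positive
                base = model.accuracy(cond, method, gold_pos)
                acc_u = float(np.sum(w * np.array([_shift(base, ui) for ui in u_vals])))
            if method == "paper":
                acc_u *= 1.0 - model.not_assessed_prob
            total += acc_u
        out[cond] = total / n
    return out
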