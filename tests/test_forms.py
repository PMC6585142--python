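from datetime import date, datetime

import pytest

from neocds.forms import (
    AssessmentRecord,
    FormItem,
    FormSchema,
    FormSchemaError,
    completeness_report,
    engine_fill,
    load_bundled_schema,
    next_item,
    summary_report,
    validate_response,
)
from neocds.manage import build_plan

from conftest import make_profile


@pytest.fixture(scope="module")
def schema():
    return load_bundled_schema()


def _mobile_answers(healthy_case):
    ans = {
        "infant_id": healthy_case.infant_id,
        "sex": healthy_case.sex.value,
        "birth_datetime": healthy_case.birth_datetime,
        "assessment_datetime": healthy_case.assessment_datetime,
        "lmp_known": "yes" if healthy_case.lmp_date else "no",
        "lmp_date": healthy_case.lmp_date,
        "birth_weight_g": healthy_case.birth_weight_g,
        "current_weight_g": healthy_case.current_weight_g,
        "foot_length_mm": healthy_case.foot_length_mm,
        "temperature_unit": healthy_case.temperature_unit.value,
        "temperature_value": healthy_case.temperature_value,
        "breath_count_60s": healthy_case.breath_count_60s,
        "kmc_counseled": "yes",
        "cup_feeding_counseled": "yes",
    }
    for group in ("signs", "feeding_intolerance_items", "breastfeeding_items"):
        for k, v in getattr(healthy_case, group).items():
            ans[k] = v.value
    return ans


def test_first_item_of_empty_form(schema):
    assert next_item(schema, {}) == "infant_id"


def test_unknown_answer_key_is_schema_error(schema):
    with pytest.raises(FormSchemaError):
        next_item(schema, {"no_such_item": 1})


def test_skip_predicates_must_reference_earlier_items():
    with pytest.raises(FormSchemaError):
        FormSchema(
            [
                FormItem(id="a", skip={"item": "b", "op": "eq", "value": 1}),
                FormItem(id="b"),
            ]
        )


def test_small_baby_section_skipped_for_non_small(schema, healthy_case):
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    assert answers["is_small"] == "no"
    assert "kmc_counseled" not in answers  # section skipped entirely


def test_small_baby_section_asked_for_small(schema, healthy_case):
    healthy_case.birth_weight_g = 2300
    healthy_case.current_weight_g = 2250
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    assert answers["is_small"] == "yes"
    assert answers["kmc_counseled"] == "yes"


def test_lmp_section_skipped_when_unknown(schema, healthy_case):
    healthy_case.lmp_date = None
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    assert "lmp_date" not in answers and "gestational_age_weeks" not in answers


def test_engine_requires_answers_before_advancing(schema, healthy_case):
    src = _mobile_answers(healthy_case)
    del src["breath_count_60s"]
    with pytest.raises(FormSchemaError, match="breath_count_60s"):
        engine_fill(schema, src)


def test_engine_walk_terminates_with_strict_progress(schema, healthy_case):
    answers = {}
    src = _mobile_answers(healthy_case)
    from neocds.forms import COMPUTED_FIELDS

    seen = set()
    for _ in range(len(schema.items) + 1):
        item_id = next_item(schema, answers)
        if item_id is None:
            break
        assert item_id not in seen  # progress: never revisit
        seen.add(item_id)
        item = schema[item_id]
        answers[item_id] = (
            COMPUTED_FIELDS[item.compute](answers) if item.compute else src[item_id]
        )
    assert next_item(schema, answers) is None


def test_double_entry_mismatch_is_blocking(schema):
    item = schema["birth_weight_g"]
    assert validate_response(item, 2500, previous_entry=2500) == []
    issues = validate_response(item, 2600, previous_entry=2500)
    assert any(i.rule == "double_entry" and i.blocking for i in issues)


def test_range_violation_blocks_and_soft_range_warns(schema):
    temp = schema["temperature_value"]
    hard = validate_response(temp, 200)
    assert any(i.rule == "range" and i.blocking for i in hard)
    soft = validate_response(temp, 27)  # legal but implausible
    assert soft and all(not i.blocking for i in soft)


def test_computed_fields_match_direct_calculation(schema, healthy_case):
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    assert answers["postnatal_age_days"] == 6
    assert answers["gestational_age_weeks"] == pytest.approx(40.0, abs=0.1)
    assert answers["weight_change_percent"] == pytest.approx(-1.6, abs=0.05)


# --- completeness audit


def _record(method="mobile", answers=None, recs=("follow-up",)):
    return AssessmentRecord(
        method=method,
        chw_id="CHW01",
        infant_id="I1",
        answers=answers or {},
        recommendations=list(recs),
        start_time=datetime(2017, 3, 10, 9, 0),
        end_time=datetime(2017, 3, 10, 9, 20),
    )


def test_engine_built_record_audits_fully_complete(schema, healthy_case):
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    flags = completeness_report(_record(answers=answers))
    assert flags.full_assessment is True
    assert flags.ga_calculated_if_lmp is True


def test_missing_respiratory_rate_breaks_full_assessment(schema, healthy_case):
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    del answers["breath_count_60s"]
    flags = completeness_report(_record(answers=answers))
    assert flags.rr_recorded is False
    assert flags.full_assessment is False


def test_lmp_recorded_without_ga_calculation(schema, healthy_case):
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    del answers["gestational_age_weeks"]
    flags = completeness_report(_record(answers=answers))
    assert flags.ga_calculated_if_lmp is False


def test_ga_flag_vacuous_without_lmp(schema, healthy_case):
    healthy_case.lmp_date = None
    answers = engine_fill(schema, _mobile_answers(healthy_case))
    flags = completeness_report(_record(answers=answers))
    assert flags.ga_calculated_if_lmp is None


def test_completeness_is_monotone_in_recorded_answers(schema, healthy_case):
    """Adding a recorded answer never flips a completeness flag off."""
    full = engine_fill(schema, _mobile_answers(healthy_case))
    partial = {k: v for k, v in full.items() if k not in ("breath_count_60s", "poor_movement")}
    f_partial = completeness_report(_record(answers=partial)).model_dump()
    f_full = completeness_report(_record(answers=full)).model_dump()
    for flag, before in f_partial.items():
        if before is True:
            assert f_full[flag] is True, flag


# --- summary text


def test_summary_all_clear(healthy_case):
    profile = make_profile()
    plan = build_plan(profile, date(2017, 3, 10))
    text = summary_report(healthy_case, profile, plan)
    assert "No danger signs" in text
    assert "Follow-up visit: 2017-03-17" in text


def test_summary_fever_lists_referral(healthy_case):
    profile = make_profile(positive=["fever"])
    plan = build_plan(profile, date(2017, 3, 10))
    text = summary_report(healthy_case, profile, plan)
    assert "fever" in text and "REFER" in text


def test_summary_small_baby_block(healthy_case):
    profile = make_profile(positive=["small"])
    plan = build_plan(profile, date(2017, 3, 10))
    text = summary_report(healthy_case, profile, plan)
    assert "Small baby" in text
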