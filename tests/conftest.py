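import random
from datetime import date, datetime, timedelta

import pytest

from neocds.classify import CONDITIONS, ClassificationConfig, ConditionProfile, TriResult
from neocds.core import (
    BREASTFEEDING_ITEMS,
    DANGER_SIGN_ITEMS,
    FEEDING_INTOLERANCE_ITEMS,
    InfantCase,
    Sex,
    TemperatureUnit,
    TriState,
)


@pytest.fixture
def config():
    return ClassificationConfig()


@pytest.fixture
def healthy_case():
    """Term infant, all measurements normal, all signs absent."""
    return InfantCase(
        infant_id="I1",
        sex=Sex.female,
        birth_datetime=datetime(2017, 3, 1, 8, 0),
        assessment_datetime=datetime(2017, 3, 7, 10, 0),
        lmp_date=date(2016, 5, 25),
        birth_weight_g=3200,
        current_weight_g=3150,
        foot_length_mm=80,
        temperature_value=37.0,
        temperature_unit=TemperatureUnit.C,
        breath_count_60s=45,
        signs={k: TriState.absent for k in DANGER_SIGN_ITEMS},
        feeding_intolerance_items={k: TriState.absent for k in FEEDING_INTOLERANCE_ITEMS},
        breastfeeding_items={k: TriState.present for k in BREASTFEEDING_ITEMS},
    )


def make_profile(positive=(), na=(), infant_id="I1", **kwargs) -> ConditionProfile:
    """Profile builder: named conditions positive / not-assessable, rest negative."""
    conditions = {c: TriResult.negative for c in CONDITIONS}
    for c in positive:
        conditions[c] = TriResult.positive
    for c in na:
        conditions[c] = TriResult.not_assessable
    cfg = ClassificationConfig()
    danger = any(conditions[c] is TriResult.positive for c in cfg.danger_sign_set)
    kwargs.setdefault("any_danger_sign", danger)
    return ConditionProfile(infant_id=infant_id, conditions=conditions, **kwargs)


@pytest.fixture
def profile_factory():
    return make_profile


def random_case(rnd: random.Random, idx: int = 0) -> InfantCase:
    """A random, possibly incomplete case for oracle cross-checks.

    Values concentrate near classification thresholds so boundary handling is
    exercised, and every optional field / tri-state can be missing.
    """
    def maybe(value, p_missing=0.25):
        return None if rnd.random() < p_missing else value

    def tri():
        return rnd.choice([TriState.present, TriState.absent, TriState.not_assessed])

    birth_w = maybe(rnd.choice([rnd.uniform(300, 5000), 2500.0, 1500.0, 2499.0, 1499.0]))
    current_w = maybe(rnd.choice([rnd.uniform(300, 5000), 1500.0, 1499.0]))
    if birth_w is not None and rnd.random() < 0.5 and current_w is not None:
        # frequently: a plausible loss/gain relative to birth weight
        current_w = round(birth_w * (1 + rnd.uniform(-0.20, 0.08) ), 0)
    use_f = rnd.random() < 0.3
    temp_c = rnd.choice([rnd.uniform(33.0, 40.5), 38.0, 35.5, 38.1, 35.4])
    assess = datetime(2017, 3, 20, 9, 0) + timedelta(minutes=idx)
    birth_dt = assess - timedelta(days=rnd.randint(0, 35), hours=rnd.randint(0, 23))
    lmp = maybe(birth_dt.date() - timedelta(days=rnd.randint(180, 320)), 0.4)
    return InfantCase(
        infant_id=f"R{idx}",
        sex=rnd.choice(list(Sex)),
        birth_datetime=birth_dt,
        assessment_datetime=assess,
        lmp_date=lmp,
        birth_weight_g=birth_w,
        current_weight_g=current_w,
        foot_length_mm=maybe(rnd.choice([rnd.uniform(50, 100), 74.0, 73.9])),
        temperature_value=maybe(round(temp_c * 9 / 5 + 32, 1) if use_f else round(temp_c, 1)),
        temperature_unit=TemperatureUnit.F if use_f else TemperatureUnit.C,
        breath_count_60s=maybe(rnd.choice([rnd.randint(20, 100), 60, 61])),
        signs={k: tri() for k in DANGER_SIGN_ITEMS},
        feeding_intolerance_items={k: tri() for k in FEEDING_INTOLERANCE_ITEMS},
        breastfeeding_items={k: tri() for k in BREASTFEEDING_ITEMS},
    )
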