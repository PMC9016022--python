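import datetime

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from idda.data_model import IggSubstitution, VisitRecord

settings.register_profile(
    "idda",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("idda")


def make_record(**overrides) -> VisitRecord:
    """A conforming all-zero visit record, with keyword overrides."""
    base = dict(
        patient_id="P001",
        visit_date=datetime.date(2021, 3, 1),
        therapy_phase=None,
        organ_grades=(0,) * 14,
        performance_scale=100,
        hospital_days_per_100=0.0,
        icu_days_per_100=0.0,
        igg_substitution=IggSubstitution.NONE,
        chronic_infestation=0,
        other_organ_dysfunction=0,
        nutrition_status=0,
        malignancy=False,
    )
    base.update(overrides)
    return VisitRecord(**base)


@pytest.fixture
def zero_record() -> VisitRecord:
    return make_record()


@st.composite
def valid_records(draw, allow_missing: bool = False):
    """Admissible visit records over the full grading ranges.

    Performance values are decile-stepped so the record carries no
    findings at all (non-decile values are admissible but warned about).
    """
    grade = st.integers(0, 4)
    if allow_missing:
        grade = st.one_of(st.none(), grade)
    grades = tuple(draw(grade) for _ in range(14))
    hosp = draw(st.floats(0, 100, allow_nan=False, allow_subnormal=False))
    icu = draw(st.floats(0, 100 - hosp, allow_nan=False, allow_subnormal=False))
    return make_record(
        organ_grades=grades,
        performance_scale=draw(st.sampled_from(range(10, 101, 10))),
        hospital_days_per_100=hosp,
        icu_days_per_100=icu,
        igg_substitution=draw(st.sampled_from(list(IggSubstitution))),
        chronic_infestation=draw(grade),
        other_organ_dysfunction=draw(grade),
        nutrition_status=draw(grade),
        malignancy=draw(st.booleans()),
    )
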