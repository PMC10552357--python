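import datetime as dt

import pytest
from hypothesis import settings

from phenoforge.synthetic import CohortConfig, generate_cohort
from phenoforge.types import ClinicalRecord, CodeSystem, Label, PatientChart, Source

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(
    pid="P1",
    source=Source.BILLING,
    date=dt.date(2018, 1, 10),
    code="",
    code_system=None,
    text="",
):
    if code_system is None:
        if not code:
            code_system = CodeSystem.NONE
        elif code[0].isalpha():
            code_system = CodeSystem.ATC
        else:
            code_system = CodeSystem.ICD9CM
    return ClinicalRecord(pid, source, date, code_system, code, text)


def make_chart(records=(), pid="P1", age=50, label=Label.UNLABELLED):
    return PatientChart(pid, age, "F", list(records), label)


@pytest.fixture
def chart_factory():
    return make_chart


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def full_cohort():
    """Study-scale synthetic cohort (n=2,776, prevalence 0.19)."""
    return generate_cohort(CohortConfig(n_patients=2776, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for fast structural tests."""
    return generate_cohort(CohortConfig(n_patients=300, seed=7))
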