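import datetime as dt

import pytest

import skelevent as sk

DX = dt.date(2005, 1, 15)
STUDY_END = dt.date(2010, 12, 31)


@pytest.fixture(scope="session")
def codebook():
    return sk.default_codebook()


@pytest.fixture
def base_case():
    return sk.make_definition("base_case")


@pytest.fixture
def alternative():
    return sk.make_definition("alternative")


def make_patient(
    pid="P1",
    dx=DX,
    age=70,
    death=None,
    enroll_start=None,
    enroll_end=None,
    hmo=None,
    **kwargs,
):
    """A clean included-by-default patient; override fields to break rules."""
    enroll_start = enroll_start or dx - dt.timedelta(days=500)
    enroll_end = enroll_end or STUDY_END
    return sk.Patient(
        patient_id=pid,
        diagnosis_date=dx,
        age_at_diagnosis=age,
        death_date=death,
        ab_enrollment=(sk.DateInterval(enroll_start, enroll_end),),
        hmo_intervals=(sk.DateInterval(*hmo),) if hmo else (),
        **kwargs,
    )


_counter = iter(range(10**6))


def make_claim(pid, day, code, system=sk.CodeSystem.ICD9_DX, dx=DX):
    """Claim on diagnosis-relative ``day`` (int) or an absolute date."""
    date = dx + dt.timedelta(days=day) if isinstance(day, int) else day
    return sk.Claim(f"C{next(_counter)}", pid, date, sk.normalize_code(code), system)


@pytest.fixture
def single_patient_cohort(codebook):
    """One clean patient with an empty claim stream, already selected."""
    p = make_patient()
    result = sk.select_cohort([p], [], codebook)
    return p, result
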