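import numpy as np
import pytest

from albupred import (
    PatientRecord,
    UrineMeasurement,
    derive_ratios,
    load_published_model,
)


@pytest.fixture(scope="session")
def all_model():
    return load_published_model("all")


@pytest.fixture(scope="session")
def nd_model():
    return load_published_model("non_diabetic")


@pytest.fixture(scope="session")
def dm_model():
    return load_published_model("diabetic")


@pytest.fixture
def toy_scores():
    """Tiny two-class instance: positives {3, 5}, negatives {1, 2, 4}."""
    scores = np.array([3.0, 5.0, 1.0, 2.0, 4.0])
    labels = np.array([1, 1, 0, 0, 0], dtype=bool)
    return scores, labels


def make_patient(pid, upcr_uacr, *, age=60, sex="male", diabetes=False,
                 egfr=55.0, days=(0, 80, 160)):
    """Build a PatientRecord from (uPCR g/gCr, uACR mg/gCr) visit pairs.

    Concentrations are back-computed through a fixed urinary creatinine
    of 100 mg/dl so derive_ratios reproduces the requested ratios exactly.
    """
    visits = [
        derive_ratios(UrineMeasurement(
            day_index=day, uP=u * 100.0, uAlb=a, uCr=100.0))
        for day, (u, a) in zip(days, upcr_uacr)
    ]
    return PatientRecord(
        id=pid, age=age, sex=sex, diabetes=diabetes,
        serum_cr=[(d, 1.0) for d in days],
        egfr_series=[(d, egfr) for d in days],
        visits=visits,
    )


@pytest.fixture
def small_cohort():
    """Six patients spanning normo/micro/macro with clean ratio structure."""
    return [
        make_patient("A", [(0.02, 8), (0.03, 12), (0.04, 15)]),
        make_patient("B", [(0.08, 40), (0.10, 55), (0.09, 48)]),
        make_patient("C", [(0.05, 12), (0.09, 45), (0.10, 38)]),
        make_patient("D", [(0.30, 350), (0.40, 420), (0.35, 380)], egfr=35),
        make_patient("E", [(0.03, 10), (0.06, 50), (0.45, 400)], egfr=40),
        make_patient("F", [(0.01, 5), (0.02, 12), (0.02, 29)], age=82,
                     sex="female"),
    ]
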