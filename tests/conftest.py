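import numpy as np
import pytest

from setupcorr import CorrectionPolicy, SetupError6DoF, TreatmentCourse


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture
def enal_policy():
    return CorrectionPolicy("enal")


@pytest.fixture
def enal_pp_policy():
    return CorrectionPolicy("enal_pp")


def make_course(matrix, patient_id="p0"):
    return TreatmentCourse.from_matrix(patient_id, np.asarray(matrix, dtype=float))


@pytest.fixture
def constant_course():
    """30 fractions, constant systematic error, no random component."""
    matrix = np.tile([1.0, -2.0, 0.5, 0.8, -0.6, 0.3], (30, 1))
    return make_course(matrix, "const")


@pytest.fixture
def trend_course():
    """30 fractions, pure linear trend 0.1 deg/fraction on the rotations."""
    f = np.arange(1, 31, dtype=float)
    matrix = np.zeros((30, 6))
    matrix[:, 3:] = 0.1 * f[:, None]
    return make_course(matrix, "trend")


@pytest.fixture
def noisy_population(rng):
    """Small population with per-patient offsets plus day-to-day scatter."""
    courses = []
    for p in range(12):
        S = rng.normal(0.0, [2, 2, 2, 0.9, 0.8, 0.8])
        eps = rng.normal(0.0, [1, 1, 1, 0.4, 0.4, 0.4], size=(30, 6))
        courses.append(make_course(S + eps, f"pt{p:02d}"))
    return courses
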