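import numpy as np
import pytest

from eegtransfer.cohort import SubjectProfile, generate_cohort, generate_subject
from eegtransfer.encode import RasterSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 subjects, 20 s each: enough for one 7:1 split with 8 windows each."""
    return generate_cohort(8, 8, class_effect=1.5, shift_sd=0.5, seed=11,
                           duration_s=20.0)


@pytest.fixture(scope="session")
def one_recording():
    profile = SubjectProfile("S0", "healthy", seed=42)
    return generate_subject(profile, duration_s=30.0, fs=250.0)


@pytest.fixture
def small_raster():
    return RasterSpec(width=48, height=48)


@pytest.fixture
def random_window(rng):
    """A normalized 3×250 window with exact endpoints 0 and 1 per channel."""
    w = rng.uniform(0.05, 0.95, size=(3, 250))
    w[:, 0] = 0.0
    w[:, 1] = 1.0
    return w
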