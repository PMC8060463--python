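import numpy as np
import pytest

from sdcae import SignalSpec, build_dataset, generate_recording, make_toy_cohort
from sdcae.types import SeizureInterval


@pytest.fixture(scope="session")
def toy_cohort():
    """Small deterministic cohort: 3 subjects, 2 seizures each."""
    return make_toy_cohort(n_subjects=3, seizures_per_subject=2, seed=7)


@pytest.fixture(scope="session")
def toy_dataset(toy_cohort):
    """1 s segment dataset built end-to-end from the toy cohort."""
    return build_dataset(toy_cohort, duration_s=1, seed=7)


@pytest.fixture(scope="session")
def single_recording():
    """One 120 s recording with a 30 s seizure."""
    spec = SignalSpec(duration_s=120.0, seed=3)
    return generate_recording(spec, [SeizureInterval(20.0, 50.0)])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
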