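import numpy as np
import pytest

from trajphen import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant cohort shared by read-only tests."""
    return generate_cohort(SimConfig(n_participants=40, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
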