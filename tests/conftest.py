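import numpy as np
import pytest

from actipattern.simulate import SyntheticConfig, generate_spectrum_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic spectrum cohort at package defaults (seed 0)."""
    return generate_spectrum_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A smaller cohort for model-fitting tests that repeat many times."""
    return generate_spectrum_dataset(SyntheticConfig(n_participants=200, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
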