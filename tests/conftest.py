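import numpy as np
import pytest

from nmrelp import PopulationConfig, sample_population


@pytest.fixture(scope="session")
def default_config():
    return PopulationConfig.default()


@pytest.fixture(scope="session")
def small_population(default_config):
    """120 samples from the default population (truths only until rendered)."""
    return sample_population(120, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
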