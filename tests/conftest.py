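import numpy as np
import pytest

from cernaforge.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast but complete study: all three groups, planted circuits."""
    return SimConfig(seed=3, n_genes=40, n_circ=8, n_mirnas=8, depth=2e4,
                     circ_reads_mean=100.0, linear_reads_mean=4.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
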