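import numpy as np
import pytest

from perfquant import AIFParams, SimConfig, generate_aif, generate_dataset
from perfquant.curves import TimeGrid


@pytest.fixture(scope="session")
def dense_grid() -> TimeGrid:
    return TimeGrid(start=0.0, dt=1.0 / 30.0, n=36001)


@pytest.fixture(scope="session")
def default_aif(dense_grid):
    return generate_aif(AIFParams(), dense_grid)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, jitter-free dataset sharing the five reference pairs."""
    return generate_dataset(
        SimConfig(n_realizations=1, master_seed=7, noise_sigma=0.0,
                  jitter_limit_s=0.0)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
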