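import numpy as np
import pytest

from pioneerkit import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_sites=80, depth=15_000, seed=11)
    truth, data = simulate(cfg)
    return cfg, truth, data
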