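import numpy as np
import pytest

from l1mosaic.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated individual: 6 clones, young donor, high depth."""
    cfg = SimulationConfig(
        n_clones=6, age_years=5.0, mean_depth=60.0, n_individuals=100, seed=11
    )
    truth, obs = simulate_dataset(cfg)
    return cfg, truth, obs


@pytest.fixture
def rng():
    return np.random.default_rng(7)
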