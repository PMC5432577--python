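import numpy as np
import pytest

from emgfatigue.synthetic import SyntheticConfig, generate_semg


@pytest.fixture(scope="session")
def default_trial():
    """One full-size synthetic trial (25 cycles, 6 channels), seed 1."""
    cfg = SyntheticConfig(seed=1)
    cyclic, mvc, truth = generate_semg(cfg)
    return cfg, cyclic, mvc, truth


@pytest.fixture(scope="session")
def small_trial():
    """A short trial (6 cycles) for cheap structural tests."""
    cfg = SyntheticConfig(seed=3, n_cycles=6)
    cyclic, mvc, truth = generate_semg(cfg)
    return cfg, cyclic, mvc, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
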