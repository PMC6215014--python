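import numpy as np
import pytest

from dhiregio import WorldConfig, make_world
from dhiregio.dhi import dhi_stack


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured world for shared read-only tests."""
    return WorldConfig(
        grid_rows=32, grid_cols=64, n_archetypes=4, n_years=4,
        n_species=400, noise_sd=0.02, qa_dropout_prob=0.1, seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture(scope="session")
def small_dhi(small_world):
    return dhi_stack(small_world.phenology)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
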