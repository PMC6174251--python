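import numpy as np
import pytest

from lcdyn.synthetic import SyntheticConfig, generate_connectome, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Miniature study: fast, but with every structural feature present."""
    return SyntheticConfig(
        n_channels=16,
        n_sources=120,
        n_rois=12,
        n_trials=40,
        edge_density=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_gt(small_config):
    return generate_connectome(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
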