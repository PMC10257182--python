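import numpy as np
import pytest

from senoscreen import SynthConfig, generate_training_table


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down study configuration for fast end-to-end tests."""
    return SynthConfig(
        n_neg=400, n_pos=24, n_features=40, n_sources=4, n_informative=12,
        effect_size=2.5, screen_size=500, screen_active_frac=0.02, seed=7,
    )


@pytest.fixture(scope="session")
def small_training(small_cfg):
    return generate_training_table(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
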