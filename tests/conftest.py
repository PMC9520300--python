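import numpy as np
import pytest

from catcpi import ModelConfig, SyntheticSpec, gen_cpi_dataset, gen_ddi_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest architecture that exercises every component (32px images)."""
    return ModelConfig(image_size=32, cnn_target_spatial=8, depth=1, heads=2,
                       droppath_rate=0.0, fr_hidden=64, batch_size=16,
                       epochs=2, seed=0)


@pytest.fixture(scope="session")
def cpi_small():
    return gen_cpi_dataset(SyntheticSpec(n_samples=48, positive_fraction=0.5, seed=11))


@pytest.fixture(scope="session")
def ddi_small():
    return gen_ddi_dataset(SyntheticSpec(n_samples=32, positive_fraction=0.25, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
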