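import numpy as np
import pytest

from cardiossl.synthetic import NoiseConfig, PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free small phantom configuration."""
    return PhantomConfig(image_size=32, n_per_class=20,
                         noise=NoiseConfig.off(), seed=101)


@pytest.fixture(scope="session")
def clean_set(clean_cfg):
    return generate_dataset(clean_cfg)


@pytest.fixture(scope="session")
def noisy_set():
    cfg = PhantomConfig(image_size=32, n_per_class=20, seed=202)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
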