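import numpy as np
import pytest

from fetalvit.model import ViTConfig, init_params
from fetalvit import phantom as ph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest model that still exercises every architectural piece."""
    return ViTConfig(
        image_size=(16, 16), patch_size=8, embed_dim=8, depth=2, heads=2,
        num_classes=3, use_cross_attention=True, cross_source=0,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return init_params(tiny_config, seed=7), tiny_config


def make_split(n, seed, proportions=None, binary=False, **kwargs):
    """Phantom draw as (train, val) array triples, 80/20."""
    samples = ph.generate_samples(n, proportions, seed=seed, **kwargs)
    imgs = np.stack([s.image for s in samples])
    y = np.array([s.class_index for s in samples])
    if binary:
        y = (y > 0).astype(int)
    sev = np.array([s.severity for s in samples])
    k = int(0.8 * n)
    return (imgs[:k], y[:k], sev[:k]), (imgs[k:], y[k:], sev[k:])


@pytest.fixture(scope="session")
def phantom_batch():
    """A small mixed-class phantom draw reused across metric tests."""
    return ph.generate_samples(24, seed=99)
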