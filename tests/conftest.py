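import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_prob_maps(rng, batch=4, height=8, width=8, num_classes=4):
    """Random valid probability maps of shape (B, H, W, C)."""
    raw = rng.gamma(1.0, 1.0, size=(batch, height, width, num_classes))
    return raw / raw.sum(axis=-1, keepdims=True)


@pytest.fixture
def prob_batch(rng):
    return random_prob_maps(rng)
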