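import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_image(rng, h=16, w=16, high=256):
    return rng.integers(0, high, size=(h, w, 3)).astype(np.uint8)


@pytest.fixture
def image_pair(rng):
    return random_image(rng), random_image(rng)
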