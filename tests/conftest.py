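import numpy as np
import pytest

from nestsentry import ImageFrame


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_frame(pixels, index=0):
    return ImageFrame(np.asarray(pixels, dtype=float), index)


@pytest.fixture
def uniform_frame():
    return make_frame(np.full((64, 64, 3), 0.5))


@pytest.fixture
def gray_frame(rng):
    g = rng.random((64, 64))
    return make_frame(np.stack([g, g, g], axis=-1))
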