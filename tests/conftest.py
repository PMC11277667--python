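import numpy as np
import pytest

from rpcalign import make_lowrank_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def smooth_blob():
    """A smooth Gaussian-blob image with usable gradients everywhere."""
    h = w = 40
    gx, gy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    return np.exp(-(((gx - 19.5) / 8.0) ** 2 + ((gy - 17.5) / 7.0) ** 2))


@pytest.fixture
def ramp_image():
    """Horizontal ramp I(x, y) = x / (w - 1)."""
    h, w = 24, 32
    gx, _ = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    return gx / (w - 1)


@pytest.fixture
def small_stack():
    return make_lowrank_stack(20, 16, 1, 6, rank=2, seed=7)
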