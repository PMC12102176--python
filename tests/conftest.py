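import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_frame(rng):
    """Smooth band-limited 64×64 frame with edge taper (registration-safe)."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0)
    w = np.hanning(64)
    return img * w[:, None] * w[None, :]
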