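import numpy as np
import pytest

from hybridseg import Mask, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume(rng):
    """Small random integer-valued volume (post-quantization regime)."""
    return Volume3D(rng.integers(0, 64, size=(6, 6, 6)).astype(float))


def make_ball(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return r <= radius


@pytest.fixture
def ball_mask():
    return Mask(make_ball((32, 32, 32), (15.5, 15.5, 15.5), 8))
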