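import numpy as np
import pytest

from spheromet import BinaryMask2D, CalibratedImage2D


def disk_mask(shape, centre, radius, pixel_size=1.0) -> BinaryMask2D:
    rr, cc = np.indices(shape)
    return BinaryMask2D(np.hypot(rr - centre[0], cc - centre[1]) <= radius, pixel_size)


def two_level_image(mask: np.ndarray, lo=10.0, hi=200.0, pixel_size=1.0) -> CalibratedImage2D:
    img = np.full(mask.shape, lo)
    img[mask] = hi
    return CalibratedImage2D(img, pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20240507)


@pytest.fixture
def blob_mask(rng):
    """A random compact blob: union of a few overlapping disks."""
    shape = (48, 48)
    m = np.zeros(shape, dtype=bool)
    for _ in range(4):
        c = rng.uniform(14, 34, size=2)
        r = rng.uniform(4, 10)
        rr, cc = np.indices(shape)
        m |= np.hypot(rr - c[0], cc - c[1]) <= r
    return BinaryMask2D(m, 1.0)
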