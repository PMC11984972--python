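import numpy as np
import pytest

from traceridges import GrayImage, traceset_from_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gray(arr):
    return GrayImage(np.asarray(arr, dtype=float))


def ts_from(mask, img=None):
    return traceset_from_mask(np.asarray(mask, dtype=bool), img=img)


def random_trace_mask(rng, shape, n_lines=3):
    """A few random straight line segments rasterised into a mask."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lines):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        length = int(rng.integers(5, max(h, w)))
        for s in range(length):
            r = int(round(r0 + s * np.sin(ang)))
            c = int(round(c0 + s * np.cos(ang)))
            if 0 <= r < h and 0 <= c < w:
                mask[r, c] = True
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask


def brute_force_distance(mask):
    """O(n^2) nearest-trace-pixel Euclidean distance for every pixel."""
    from scipy.spatial.distance import cdist

    pts = np.argwhere(mask)
    allpix = np.argwhere(np.ones_like(mask))
    d = cdist(allpix, pts).min(axis=1)
    return d.reshape(mask.shape)
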