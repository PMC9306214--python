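import numpy as np
import pytest

from nucleiws.synth import SimConfig, generate_spheroid
from nucleiws.volume_core import BinaryMask, LabelVolume


def ball_mask(shape, center, radius, z_aniso=1.0):
    zz, yy, xx = np.indices(shape)
    return ((zz - center[0]) * z_aniso) ** 2 + (yy - center[1]) ** 2 \
        + (xx - center[2]) ** 2 <= radius ** 2


@pytest.fixture(scope="session")
def small_spheroid():
    """A 12-nucleus clumped spheroid in a compact volume (shared, read-only)."""
    cfg = SimConfig(n_nuclei=12, volume_shape=(16, 96, 96), rng_seed=7)
    return generate_spheroid(cfg)


@pytest.fixture(scope="session")
def two_ball_mask():
    """Two radius-5 balls overlapping slightly: the canonical clumped pair."""
    shape = (24, 32, 24)
    m = ball_mask(shape, (11, 10, 11), 5) | ball_mask(shape, (11, 19, 11), 5)
    return BinaryMask(m, "M3D", (1.0, 1.0, 1.0), space="expanded")


def random_blob_mask(rng, shape):
    """A random smooth-ish binary mask: thresholded filtered noise."""
    from scipy import ndimage
    noise = rng.random(shape)
    smooth = ndimage.gaussian_filter(noise, 1.5)
    return smooth > np.quantile(smooth, 0.7)


def random_label_volume(rng, shape, k):
    """k blobby labels painted at random centers (labels may be missing)."""
    out = np.zeros(shape, dtype=np.int32)
    for lab in range(1, k + 1):
        c = [rng.integers(s) for s in shape]
        r = rng.integers(2, max(3, min(shape) // 2))
        zz, yy, xx = np.indices(shape)
        blob = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r ** 2
        out[blob & (out == 0)] = lab
    return out
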