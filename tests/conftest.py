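import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eyereg.imgio import GrayImage, RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_roi():
    """Factory: a ROI covering an entire h x w frame."""
    def make(h, w):
        return RegionOfInterest(np.ones((h, w), dtype=bool))
    return make


@pytest.fixture
def two_spot_image():
    """Two well-separated Gaussian spots (peaks 200 and 195) over a low
    ridge, so the saddle between them is about 50."""
    yy, xx = np.mgrid[0:40, 0:40].astype(float)
    ridge = 50.0 * np.exp(-((yy - 20) ** 2) / 800.0)
    s1 = 150.0 * np.exp(-((xx - 10) ** 2 + (yy - 20) ** 2) / 18.0)
    s2 = 145.0 * np.exp(-((xx - 30) ** 2 + (yy - 20) ** 2) / 18.0)
    return GrayImage(np.maximum(s1, s2) + ridge)


def smooth_random_image(rng, h, w, sigma=1.5, scale=200.0):
    """A tie-free smooth random field on [0, scale]."""
    import scipy.ndimage as ndi

    img = ndi.gaussian_filter(rng.normal(size=(h, w)), sigma)
    img = img - img.min()
    img = img / img.max() * scale
    # break any residual exact ties deterministically
    tiny = rng.normal(scale=1e-9, size=img.shape)
    return img + tiny
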