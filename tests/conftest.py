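import numpy as np
import pytest

from curvecad.roi_segment import RoiImage


@pytest.fixture
def rng():
    return np.random.default_rng(20130515)


@pytest.fixture
def random_roi(rng):
    """A 64x64 ROI with a square foreground patch of random texture."""
    pixels = np.zeros((64, 64))
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[8:56, 8:56] = 1
    pixels[8:56, 8:56] = 100 + 10 * rng.normal(size=(48, 48))
    return RoiImage(pixels, mask, patient_id="p0", roi_id="p0_s0_r0")
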