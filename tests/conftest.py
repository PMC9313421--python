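import numpy as np
import pytest
from skimage import draw


def disk_mask(shape, centre, radius):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(centre, radius, shape=shape)
    mask[rr, cc] = True
    return mask


@pytest.fixture
def circle_roi_small():
    """25-px-radius disk in a 64x64 frame (oracle-sized)."""
    return disk_mask((64, 64), (32, 32), 25)


@pytest.fixture
def two_lobe_roi():
    """Non-convex ROI: union of two overlapping disks, 64x64."""
    return disk_mask((64, 64), (28, 24), 14) | disk_mask((64, 64), (36, 42), 12)


@pytest.fixture
def circle_roi_large():
    """100-px-radius disk in a 256x256 frame."""
    return disk_mask((256, 256), (128, 128), 100)
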