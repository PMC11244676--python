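import numpy as np
import pytest

from metartiq import CTVolume


@pytest.fixture
def disk_volume():
    """3-slice volume with a metal disk of radius 20 voxels at the centre."""
    sl = np.full((128, 128), -50.0)
    rows, cols = np.mgrid[0:128, 0:128]
    sl[np.hypot(rows - 64, cols - 64) <= 20] = 3000.0
    return CTVolume(np.stack([sl] * 3), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
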