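import numpy as np
import pytest

from hcsmorph.preprocess import PreprocessedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair(gray, mask=None, source_id="test"):
    """Build a PreprocessedImage from a gray array (mask defaults to gray > 0)."""
    gray = np.asarray(gray, dtype=np.float64)
    if mask is None:
        mask = gray > 0
    return PreprocessedImage(gray=gray, mask=np.asarray(mask, dtype=bool),
                             otsu_threshold=0.0, source_id=source_id)


@pytest.fixture
def disc_image():
    """65x65 image holding a centered solid disc of radius 20."""
    yy, xx = np.indices((65, 65))
    mask = (xx - 32) ** 2 + (yy - 32) ** 2 <= 20**2
    return mask.astype(np.float64)


@pytest.fixture
def random_gray(rng):
    """32x32 integer-valued gray image spanning [0, 65535]."""
    img = rng.integers(0, 65536, size=(32, 32)).astype(np.float64)
    img.flat[0] = 0.0
    img.flat[1] = 65535.0
    return img
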