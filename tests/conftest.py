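import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_three_population_image(seed=1, shape=(128, 128)):
    """Tissue-like image: dark nuclei inside mid-gray cytoplasm rings on a
    bright background (means 40 / 140 / 240, sigma 8), with the
    ground-truth nuclear mask."""
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.clip(np.rint(rng.normal(240, 8, (h, w))), 0, 255)
    truth = np.full((h, w), 255, np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = [(20 + 44 * i, 20 + 44 * j) for i in range(3) for j in range(3)]
    for cy, cx in centers:
        cyt = (yy - cy) ** 2 + (xx - cx) ** 2 <= 19 ** 2
        nuc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 15 ** 2
        img[cyt] = np.clip(np.rint(rng.normal(140, 8, cyt.sum())), 0, 255)
        img[nuc] = np.clip(np.rint(rng.normal(40, 8, nuc.sum())), 0, 255)
        truth[nuc] = 0
    return img.astype(np.int64), truth
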