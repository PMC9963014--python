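import numpy as np
import pytest

from rgbfvc import RGBImage, SceneSpec, generate_scene
from rgbfvc.indices import IndexImage, get_index


@pytest.fixture
def rng():
    return np.random.default_rng(20230421)


@pytest.fixture
def random_image(rng):
    """A 16x16 random RGB image with channels in the native 8-bit domain."""
    r, g, b = rng.uniform(0, 255, size=(3, 16, 16))
    return RGBImage(red=r, green=g, blue=b)


@pytest.fixture(scope="session")
def default_scene():
    """One default 256x256 synthetic scene shared across read-only tests."""
    return generate_scene(SceneSpec(seed=11))


def make_index_image(values, name="EXG", mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    return IndexImage(values=values, index=get_index(name),
                      valid_mask=np.asarray(mask, dtype=bool))
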