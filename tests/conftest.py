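import numpy as np
import pytest

from benthoscope.raster_io import LabelMap, OrthoImage, label_index
from benthoscope.scene_sim import default_scene_config, generate_scene
from benthoscope.tiling import TilePair


@pytest.fixture(scope="session")
def small_scene():
    """A 192x192 default-appearance scene shared by read-only tests."""
    return generate_scene(default_scene_config(192, 192, seed=42))


@pytest.fixture(scope="session")
def medium_scene():
    """A 256x256 default-appearance scene for classifier tests."""
    return generate_scene(default_scene_config(256, 256, seed=7))


def make_tile(image: np.ndarray, labels: np.ndarray, row=0, col=0, region="train"):
    return TilePair(OrthoImage(image), LabelMap(labels), row, col, region=region)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_nv_tile():
    """A 16x16 all-NV tile over random image content."""
    r = np.random.default_rng(0)
    img = r.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    lab = np.full((16, 16), label_index("NV"), dtype=np.uint8)
    return make_tile(img, lab)
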