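import numpy as np
import pytest

from mapchange.georaster import GeoRaster, GeoTransform
from mapchange.synthmap import ChangeParams, SceneParams, generate_scene, render_sheet


@pytest.fixture(scope="session")
def transform() -> GeoTransform:
    return GeoTransform(0.0, 1700.0, 1.7)


@pytest.fixture(scope="session")
def small_scene():
    """2x2 km scene with all five classes present."""
    return generate_scene((2.0, 2.0), seed=11)


@pytest.fixture(scope="session")
def rendered_pair(small_scene):
    """(rgb, labels) rendering of the small scene."""
    return render_sheet(small_scene)


@pytest.fixture()
def rgb_sheet() -> GeoRaster:
    rng = np.random.default_rng(0)
    data = rng.integers(0, 256, size=(64, 80, 3), dtype=np.uint8)
    return GeoRaster(data, GeoTransform(0.0, 64 * 1.7, 1.7))
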