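import numpy as np
import pytest
from shapely.geometry import Point

from neuroplan import phantom as ph


@pytest.fixture(scope="session")
def model():
    """Default head phantom (built once; meshes and silhouette are reused)."""
    return ph.build_phantom()


@pytest.fixture(scope="session")
def silhouette(model):
    return model.silhouette()


@pytest.fixture(scope="session")
def circle25():
    """Circular reference silhouette, radius 25 mm."""
    return Point(0.0, 0.0).buffer(25.0, quad_segs=256)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240424)
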