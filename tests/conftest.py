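import numpy as np
import pytest

from cellpattern import FieldGeometry, rasterize
from cellpattern.synthetic import clust_a


@pytest.fixture(scope="session")
def clust_a_pattern():
    """The frozen four-blob fixture (800 points, centres 20 sd apart)."""
    return clust_a()


@pytest.fixture(scope="session")
def clust_a_raster(clust_a_pattern):
    """CLUST-A stamped as 6 µm nucleus disks on the 2 µm grid."""
    return rasterize(clust_a_pattern, nucleus_radius=6.0)


@pytest.fixture(scope="session")
def small_field():
    return FieldGeometry(200.0, 200.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
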