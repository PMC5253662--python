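import numpy as np
import pytest

from neuromosaic.geometry import Box3D, PointPattern


@pytest.fixture
def unit_box():
    return Box3D.cube(1.0)


@pytest.fixture
def box100():
    return Box3D.cube(100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def octant_pattern(box100):
    """8 points at the octant centres of a 100 μm cube."""
    pts = np.array([[x, y, z] for x in (25.0, 75.0)
                    for y in (25.0, 75.0) for z in (25.0, 75.0)])
    return PointPattern(pts, box100)
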