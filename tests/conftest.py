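import numpy as np
import pytest

from spacerdose.core import ImageGrid, ROISet
from spacerdose.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default 2-mm phantom, shared read-only across tests."""
    return generate_phantom(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def fine_phantom():
    """1-mm-voxel phantom (same geometry): >= 10^4 spacer voxels."""
    return generate_phantom(PhantomParams.fine(seed=7))


@pytest.fixture(scope="session")
def water_box():
    """Uniform SPR=1 box with a spherical CTV — analytic planning testbed."""
    shape, spacing = (80, 80, 60), (2.0, 2.0, 2.0)
    spr = ImageGrid(np.ones(shape), spacing, unit="SPR")
    centre = spr.index_to_world((np.asarray(shape) - 1) / 2.0)
    x = spr.axis_coordinates(0) - centre[0]
    y = spr.axis_coordinates(1) - centre[1]
    z = spr.axis_coordinates(2) - centre[2]
    r2 = x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    ctv = r2 <= 15.0**2
    rois = ROISet(spr, {"ctv": ctv})
    return spr, rois
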