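import numpy as np
import pytest

from myomap3d.myomapping import fit_wall_frame
from myomap3d.volume_io import BINARY_MASK, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def full_mask():
    def make(shape, voxel_size_um=(1.0, 1.0, 1.0)):
        return Volume3D(np.ones(shape, dtype=np.uint8), voxel_size_um, BINARY_MASK)

    return make


@pytest.fixture
def slab_frame(full_mask):
    """Default slab frame over a full lattice of the given shape."""

    def make(shape, voxel_size_um=(1.0, 1.0, 1.0)):
        return fit_wall_frame(full_mask(shape, voxel_size_um))

    return make


@pytest.fixture
def smooth_volume(rng):
    """A random volume smoothed enough to have well-behaved gradients."""
    from scipy import ndimage

    data = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2.0)
    return Volume3D(data, (1.0, 1.0, 1.0))
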