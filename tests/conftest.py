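import numpy as np
import pytest

import vascmorph as vm


@pytest.fixture(scope="session")
def tree():
    """A small tortuous default tree used by several suites."""
    return vm.generate_vessel_tree(seed=1, tortuosity_amplitude_um=2.0)


@pytest.fixture(scope="session")
def phantom(tree):
    """(volume, truth mask, tree) rasterized at 1 μm with moderate noise."""
    vol, truth = vm.rasterize_tree(tree, voxel_size_um=1.0, noise_sigma=10.0, seed=2)
    return vol, truth, tree


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_cylinder_mask(radius_um, length_um, voxel_size_um=1.0, pad_um=5.0):
    """Truth mask of a single z-axis-aligned cylinder, plus its tree.

    The segment spans the full z extent of the volume so the spherical end
    caps of the capsule rasterization fall outside it: the mask is a pure
    cylinder of the requested length.
    """
    half = radius_um + pad_um
    seg = vm.VesselSegment(
        p0=np.array([0.0, half, half]),
        p1=np.array([length_um, half, half]),
        radius_um=radius_um,
    )
    t = vm.VesselTree(segments=[seg])
    shape = (
        int(np.ceil(length_um / voxel_size_um)),
        int(np.ceil(2 * half / voxel_size_um)),
        int(np.ceil(2 * half / voxel_size_um)),
    )
    vol, truth = vm.rasterize_tree(
        t,
        voxel_size_um=voxel_size_um,
        volume_shape=shape,
        origin_um=(0.0, 0.0, 0.0),
        noise_sigma=0.0,
    )
    return vol, truth, t
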