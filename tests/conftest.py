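import numpy as np
import pytest

from archflow4d.core import VelocityField4D, VoxelMask
from archflow4d.geometry import condition_mask, extract_centerline
from archflow4d.phantom import (ArchSpec, build_arch_centerline,
                                voxelize_arch)


@pytest.fixture(scope="session")
def roman_spec():
    return ArchSpec.canonical("roman")


@pytest.fixture(scope="session")
def roman_centerline(roman_spec):
    return build_arch_centerline(roman_spec)


@pytest.fixture(scope="session")
def roman_mask(roman_centerline):
    return voxelize_arch(roman_centerline, 0.5)


@pytest.fixture(scope="session")
def roman_tree(roman_mask):
    return extract_centerline(condition_mask(roman_mask))


@pytest.fixture(scope="session")
def roman_flow_mask(roman_centerline):
    # 1 mm grid: flow scoring operates at isotropic 1 mm anyway
    return voxelize_arch(roman_centerline, 1.0)


@pytest.fixture(scope="session")
def tube_mask():
    """Straight tube of radius 5 mm along z at 0.5 mm spacing."""
    # odd grid: the tube axis passes through voxel centres (3D thinning
    # can fully erode a perfectly even-parity straight cylinder)
    n, nz = 37, 60
    ax = (np.arange(n) - n // 2) * 0.5
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    section = X ** 2 + Y ** 2 <= 25.0
    data = np.repeat(section[:, :, None], nz, axis=2)
    # axis at world x = y = 0
    return VoxelMask(data, (0.5, 0.5, 0.5), (ax[0], ax[0], 0.0))


def random_tube_field(seed: int, n: int = 24, radius: float = 8.0,
                      scale: float = 10.0) -> VelocityField4D:
    """One-frame random velocity field on a tube lumen (1 mm grid)."""
    rng = np.random.default_rng(seed)
    ax = np.arange(n)
    X, Y, _ = np.meshgrid(ax, ax, ax, indexing="ij")
    lum = (X - n // 2) ** 2 + (Y - n // 2) ** 2 <= radius ** 2
    mask = VoxelMask(lum, (1, 1, 1), (0, 0, 0))
    comps = rng.normal(0, scale, (3, 1, n, n, n)).astype(np.float32)
    comps[:, :, ~lum] = 0.0
    return VelocityField4D(comps[0], comps[1], comps[2], (1, 1, 1),
                           25.0, mask)
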