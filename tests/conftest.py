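import numpy as np
import pytest

from crumbct import PhantomSpec, VolumeMeta, generate_bun_phantom
from crumbct.segmentation import BinaryMask


@pytest.fixture(scope="session")
def small_phantom():
    """Small seeded bun phantom with ~23.5% ground-truth porosity."""
    spec = PhantomSpec(
        body_semi_axes_mm=(6.0, 5.0, 4.0),
        target_porosity_pct=23.5,
        pore_radius_median_mm=0.55,
        seed=11,
    )
    return spec, *generate_bun_phantom(spec)


def make_mask(grid: np.ndarray, spacing=(0.16, 0.16, 0.16)) -> BinaryMask:
    grid = np.asarray(grid, dtype=bool)
    return BinaryMask(grid=grid, meta=VolumeMeta(shape=grid.shape, spacing_mm=spacing))


def digitized_sphere(radius_vox: float, pad: int = 3) -> np.ndarray:
    """Boolean grid of a sphere: voxel centers within radius of the center."""
    r = int(np.ceil(radius_vox))
    n = 2 * (r + pad) + 1
    ax = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (X**2 + Y**2 + Z**2) <= radius_vox**2


def solid_cylinder(radius_vox: int, length_vox: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius_vox + pad) + 1
    grid = np.zeros((n, n, length_vox + 2 * pad), dtype=bool)
    ax = np.arange(n) - (n - 1) / 2
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    grid[:, :, pad : pad + length_vox] = ((X**2 + Y**2) <= radius_vox**2)[:, :, None]
    return grid


def brute_force_opening(grid: np.ndarray, radius_vox: float) -> np.ndarray:
    """Definition-level opening: shift-and-AND erosion, shift-and-OR dilation.

    Voxels outside the grid count as background, matching the pipeline's
    border convention.  Independent of scipy's morphology implementation.
    """
    r = int(np.floor(radius_vox))
    offsets = [
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-r, r + 1)
        if dx * dx + dy * dy + dz * dz <= radius_vox * radius_vox
    ]

    def shifted(a: np.ndarray, off, fill: bool) -> np.ndarray:
        out = np.full_like(a, fill)
        src = [slice(max(-o, 0), a.shape[i] - max(o, 0)) for i, o in enumerate(off)]
        dst = [slice(max(o, 0), a.shape[i] - max(-o, 0)) for i, o in enumerate(off)]
        out[tuple(dst)] = a[tuple(src)]
        return out

    eroded = np.ones_like(grid)
    for off in offsets:
        eroded &= shifted(grid, off, False)
    opened = np.zeros_like(grid)
    for off in offsets:
        opened |= shifted(eroded, tuple(-o for o in off), False)
    return opened
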