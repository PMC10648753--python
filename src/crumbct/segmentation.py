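"""Grayscale segmentation chain for porous-crumb CT volumes.

The pore phase of a bun cannot be recovered by a single threshold: interior
pores and exterior air share the same attenuation, so both fall in the same
low-GSV band.  The chain used here mirrors standard CT practice:

1. band-threshold the solid matrix (default −750..−250 GSV),
2. fill enclosed holes to obtain the whole-sample mask,
3. subtract the matrix from the filled mask (mask arithmetic) to isolate
   interior pores,
4. open with a ball element to separate pores touching at thin necks,
5. label connected components for per-pore morphometry.

A balanced-histogram threshold is provided as the automatic alternative to
a hand-picked band edge.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .volume_io import VolumeMeta, VoxelVolume

log = logging.getLogger(__name__)


@dataclasses.dataclass
class GSVHistogram:
    """Histogram of grayscale values over half-open integer bins."""

    bin_edges: np.ndarray  # length n_bins + 1, increasing integers
    counts: np.ndarray  # length n_bins, non-negative

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have one entry fewer than bin_edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclasses.dataclass
class BinaryMask:
    """Boolean voxel mask sharing the source volume's metadata."""

    grid: np.ndarray
    meta: VolumeMeta

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.shape != self.meta.shape:
            raise ValueError(f"mask shape {self.grid.shape} != meta shape {self.meta.shape}")

    @property
    def count(self) -> int:
        return int(self.grid.sum())


@dataclasses.dataclass
class LabelMap:
    """Integer labels 1..n_labels over a mask; 0 is background."""

    grid: np.ndarray
    n_labels: int
    meta: VolumeMeta

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int32)
        if self.grid.shape != self.meta.shape:
            raise ValueError(f"label shape {self.grid.shape} != meta shape {self.meta.shape}")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def compute_histogram(
    volume: VoxelVolume, bin_width: int = 25, region: BinaryMask | None = None
) -> GSVHistogram:
    """Histogram the volume's GSVs (optionally within a region mask).

    Bins are half-open ``[edge, edge + bin_width)`` starting at the minimum
    included value; counts conserve the number of histogrammed voxels.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if region is not None:
        if region.grid.shape != volume.values.shape:
            raise ValueError("region shape differs from volume shape")
        data = volume.values[region.grid]
        if data.size == 0:
            raise ValueError("region is empty")
    else:
        data = volume.values.ravel()
    vmin = int(data.min())
    vmax = int(data.max())
    n_bins = (vmax - vmin) // bin_width + 1
    edges = vmin + bin_width * np.arange(n_bins + 1, dtype=np.int64)
    counts, _ = np.histogram(data, bins=edges)
    return GSVHistogram(bin_edges=edges, counts=counts)


def balanced_histogram_threshold(hist: GSVHistogram) -> int:
    """Balanced-scale threshold of a (typically bimodal) histogram.

    The histogram is viewed as masses on a scale whose endpoints are the
    outermost nonempty bins.  Repeatedly, the masses strictly left and
    strictly right of the current range midpoint are compared and the outer
    bin of the heavier side is removed (the midpoint shifts as the range
    shrinks).  On exact balance both outer bins are removed symmetrically,
    except that a balanced two-bin range drops the right bin.  Returns the
    lower edge of the bin the range collapses to.
    """
    counts = hist.counts
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 0:
        raise ValueError("histogram has no nonzero counts")
    cumsum = np.concatenate([[0], np.cumsum(counts)])

    def mass(a: int, b: int) -> int:  # inclusive bin range, empty if a > b
        if a > b:
            return 0
        return int(cumsum[b + 1] - cumsum[a])

    i_s, i_e = int(nonzero[0]), int(nonzero[-1])
    while i_e > i_s:
        mid2 = i_s + i_e  # 2 * midpoint, avoids float comparisons
        # bins strictly left / right of the midpoint; an exactly central
        # bin (mid2 even) belongs to neither pan
        w_l = mass(i_s, (mid2 - 1) // 2)
        w_r = mass(mid2 // 2 + 1, i_e)
        if w_l > w_r:
            i_s += 1
        elif w_r > w_l:
            i_e -= 1
        elif i_e - i_s == 1:
            i_e -= 1
        else:
            i_s += 1
            i_e -= 1
    return int(hist.bin_edges[i_s])


def band_threshold(
    volume: VoxelVolume, lo: int, hi: int, region: BinaryMask | None = None
) -> BinaryMask:
    """Mask of voxels with ``lo <= GSV <= hi`` (closed interval)."""
    if lo > hi:
        raise ValueError(f"band lo {lo} > hi {hi}")
    grid = (volume.values >= lo) & (volume.values <= hi)
    if region is not None:
        if region.grid.shape != grid.shape:
            raise ValueError("region shape differs from volume shape")
        grid &= region.grid
    return BinaryMask(grid=grid, meta=volume.meta)


def fill_holes(mask: BinaryMask, background_connectivity: int = 6) -> BinaryMask:
    """Fill background cavities not connected to any volume face.

    The background flood uses the given connectivity (6 by default, the
    dual of 26-connected foreground).  The result is a superset of the
    input and the operation is idempotent.
    """
    structure = _structure(background_connectivity)
    filled = ndimage.binary_fill_holes(mask.grid, structure=structure)
    return BinaryMask(grid=filled, meta=mask.meta)


def mask_difference(filled: BinaryMask, matrix: BinaryMask) -> BinaryMask:
    """``filled AND NOT matrix`` — the interior pore phase.

    Matrix voxels outside the filled mask are unexpected; they are logged
    and clipped (they cannot contribute to the difference anyway).
    """
    if filled.grid.shape != matrix.grid.shape:
        raise ValueError(
            f"shape mismatch: filled {filled.grid.shape} vs matrix {matrix.grid.shape}"
        )
    stray = int((matrix.grid & ~filled.grid).sum())
    if stray:
        log.warning("mask_difference: %d matrix voxels outside the filled mask (clipped)", stray)
    return BinaryMask(grid=filled.grid & ~matrix.grid, meta=filled.meta)


def ball_element(radius_vox: float) -> np.ndarray:
    """Digitized Euclidean ball: voxel included iff its center is within
    ``radius_vox`` of the element center."""
    if radius_vox <= 0:
        raise ValueError(f"ball radius must be > 0, got {radius_vox}")
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (dx * dx + dy * dy + dz * dz) <= radius_vox * radius_vox


def binary_opening(mask: BinaryMask, ball_radius_vox: float = 3.0) -> BinaryMask:
    """Morphological opening (erosion then dilation) with a ball element.

    Separates pores joined by necks thinner than the ball and removes
    speckle smaller than the ball.  Voxels outside the grid count as
    background for both passes.  Anti-extensive and idempotent.
    """
    elem = ball_element(ball_radius_vox)
    eroded = ndimage.binary_erosion(mask.grid, structure=elem, border_value=0)
    opened = ndimage.binary_dilation(eroded, structure=elem, border_value=0)
    return BinaryMask(grid=opened, meta=mask.meta)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Connected-component labels, deterministically ordered.

    Components are maximal under the chosen connectivity; labels are
    renumbered so that label k is the k-th component encountered in raster
    (C) order of the grid.
    """
    structure = _structure(connectivity)
    raw, n = ndimage.label(mask.grid, structure=structure)
    if n > 0:
        flat = raw.ravel()
        labels, first = np.unique(flat, return_index=True)
        order = labels[np.argsort(first)]
        order = order[order != 0]
        lut = np.zeros(n + 1, dtype=np.int32)
        lut[order] = np.arange(1, n + 1, dtype=np.int32)
        raw = lut[raw]
    return LabelMap(grid=raw, n_labels=int(n), meta=mask.meta)
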