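"""Voxel volumes and their on-disk representations.

A reconstructed CT scan is a 3D grid of signed 16-bit grayscale values
(GSVs), proportional to X-ray attenuation and hence local density.  The
scanner writes headerless RAW files; shape, spacing and byte order live in
a small plain-text sidecar next to the data file.  This module provides the
in-memory container (:class:`VoxelVolume`), RAW and slice-stack readers,
and cropping.

Conventions
-----------
* ``values`` is indexed ``[x, y, z]`` with shape ``(nx, ny, nz)``.
* On disk, x varies fastest (then y, then z), i.e. one xy slice after
  another along z.
* Crop boxes are half-open ``[lo, hi)`` with 0-based indices.
* Byte order defaults to little-endian and is recorded in the sidecar.
"""

from __future__ import annotations

import dataclasses
import math
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

GSV_DTYPE = np.int16
GSV_MIN = -32768
GSV_MAX = 32767

#: sidecar filename suffix appended to the RAW path
SIDECAR_SUFFIX = ".meta"


@dataclasses.dataclass(frozen=True)
class VolumeMeta:
    """Geometry and value-range metadata of a voxel volume.

    Parameters
    ----------
    shape:
        Grid size ``(nx, ny, nz)`` in voxels.
    spacing_mm:
        Physical voxel edge lengths in mm; defaults to the 160 µm
        isotropic spacing of the desktop scanner.
    gsv_min, gsv_max:
        Admissible grayscale range (full int16 by default).
    byte_order:
        ``"little"`` or ``"big"``; byte order of the RAW file.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (0.16, 0.16, 0.16)
    gsv_min: int = GSV_MIN
    gsv_max: int = GSV_MAX
    byte_order: str = "little"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive reals, got {self.spacing_mm}")
        if not self.gsv_min < self.gsv_max:
            raise ValueError(f"gsv_min must be < gsv_max, got {self.gsv_min}, {self.gsv_max}")
        if self.byte_order not in ("little", "big"):
            raise ValueError(f"byte_order must be 'little' or 'big', got {self.byte_order!r}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_shape(self, shape: tuple[int, int, int]) -> "VolumeMeta":
        return dataclasses.replace(self, shape=tuple(int(n) for n in shape))


@dataclasses.dataclass
class VoxelVolume:
    """A 3D grid of GSVs with physical metadata.

    ``values[x, y, z]`` is the GSV of the voxel whose center sits at
    ``((x + 0.5) * dx, (y + 0.5) * dy, (z + 0.5) * dz)`` mm.
    """

    meta: VolumeMeta
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=GSV_DTYPE)
        if self.values.shape != self.meta.shape:
            raise ValueError(
                f"values shape {self.values.shape} != meta shape {self.meta.shape}"
            )
        vmin, vmax = int(self.values.min(initial=0)), int(self.values.max(initial=0))
        if vmin < self.meta.gsv_min or vmax > self.meta.gsv_max:
            raise ValueError(
                f"GSVs [{vmin}, {vmax}] outside [{self.meta.gsv_min}, {self.meta.gsv_max}]"
            )


def _dtype(meta: VolumeMeta) -> np.dtype:
    return np.dtype(GSV_DTYPE).newbyteorder("<" if meta.byte_order == "little" else ">")


def read_raw(path: str | os.PathLike, meta: VolumeMeta) -> VoxelVolume:
    """Read a headerless RAW volume.

    The file must contain exactly ``nx * ny * nz`` int16 values with x
    varying fastest; a size mismatch raises with the expected and actual
    byte counts.
    """
    path = Path(path)
    nx, ny, nz = meta.shape
    expected = nx * ny * nz * 2
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{path}: expected {expected} bytes for shape {meta.shape} (int16), got {actual}"
        )
    flat = np.fromfile(path, dtype=_dtype(meta))
    values = flat.reshape((nz, ny, nx)).transpose(2, 1, 0).astype(GSV_DTYPE)
    return VoxelVolume(meta=meta, values=values)


def write_raw(volume: VoxelVolume, path: str | os.PathLike) -> Path:
    """Write a volume as headerless RAW plus a plain-text sidecar.

    Returns the sidecar path.  ``read_raw`` on the pair reproduces the
    volume bit-exactly.
    """
    path = Path(path)
    disk = volume.values.transpose(2, 1, 0).astype(_dtype(volume.meta))
    disk.tofile(path)
    sidecar = Path(str(path) + SIDECAR_SUFFIX)
    m = volume.meta
    sidecar.write_text(
        "shape: {} {} {}\n".format(*m.shape)
        + "spacing_mm: {} {} {}\n".format(*m.spacing_mm)
        + "dtype: int16\n"
        + f"byte_order: {m.byte_order}\n"
        + f"gsv_min: {m.gsv_min}\n"
        + f"gsv_max: {m.gsv_max}\n"
        + "axis_order: x-fastest\n"
    )
    return sidecar


def read_sidecar(path: str | os.PathLike) -> VolumeMeta:
    """Parse a sidecar written by :func:`write_raw`."""
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    return VolumeMeta(
        shape=tuple(int(t) for t in fields["shape"].split()),
        spacing_mm=tuple(float(t) for t in fields["spacing_mm"].split()),
        gsv_min=int(fields.get("gsv_min", GSV_MIN)),
        gsv_max=int(fields.get("gsv_max", GSV_MAX)),
        byte_order=fields.get("byte_order", "little"),
    )


def load_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read a RAW volume using the sidecar next to it."""
    return read_raw(path, read_sidecar(str(path) + SIDECAR_SUFFIX))


_SLICE_EXTENSIONS = (".tif", ".tiff", ".png")


def read_slice_stack(
    directory: str | os.PathLike,
    spacing_mm: tuple[float, float, float] = (0.16, 0.16, 0.16),
) -> VoxelVolume:
    """Assemble a volume from a directory of 2D grayscale slices.

    Lexicographic filename order defines the z (slice) axis; image rows map
    to y and columns to x.  All slices must share one shape; an offender is
    named in the error.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS
    )
    if not files:
        raise ValueError(f"{directory}: no slice images ({'/'.join(_SLICE_EXTENSIONS)}) found")
    slices = []
    shape0 = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise ValueError(f"{f}: expected a 2D grayscale image, got shape {img.shape}")
        if shape0 is None:
            shape0 = img.shape
        elif img.shape != shape0:
            raise ValueError(f"{f}: slice shape {img.shape} differs from first slice {shape0}")
        slices.append(img.astype(np.int32))
    stack = np.stack(slices, axis=0)  # (nz, ny, nx)
    values = stack.transpose(2, 1, 0)
    meta = VolumeMeta(shape=values.shape, spacing_mm=spacing_mm)
    return VoxelVolume(meta=meta, values=values.astype(GSV_DTYPE))


def crop(
    volume: VoxelVolume, lo: tuple[int, int, int], hi: tuple[int, int, int]
) -> VoxelVolume:
    """Extract the half-open box ``[lo, hi)``; spacing is preserved."""
    lo = tuple(int(v) for v in lo)
    hi = tuple(int(v) for v in hi)
    for axis in range(3):
        if not (0 <= lo[axis] < hi[axis] <= volume.meta.shape[axis]):
            raise ValueError(
                f"crop box [{lo}, {hi}) out of bounds on axis {axis} "
                f"for shape {volume.meta.shape}"
            )
    values = volume.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    meta = volume.meta.with_shape(values.shape)
    return VoxelVolume(meta=meta, values=values)
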