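"""Voxel grid container and multi-page TIFF z-stack I/O.

Axis convention: arrays are indexed ``(z, y, x)`` with 0-based indices; the
physical step per axis is ``spacing = (dz, dy, dx)`` in nanometres.  Axial
sampling is normally coarser than lateral sampling (e.g. 500 nm z steps at
108 nm pixels), so spacing must travel with the data through every reslice
and projection.  All lengths are carried in nm internally and reported in
micrometres at the interface level.

Voxel spacing is metadata supplied by the caller (CLI flag or config);
TIFF resolution tags are only consulted to warn on a gross mismatch,
because the tag dialects written by acquisition software vary too much to
be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import StackFormatError, ValidationError

#: axis name -> array axis for (z, y, x) ordered data
AXES = {"z": 0, "y": 1, "x": 2}


@dataclass
class VoxelGrid:
    """A 3D intensity image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities.  Float arrays are allowed internally;
        quantization to the declared bit depth happens only on export.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel pitch in nm, all strictly positive.
    bit_depth : int
        8 or 16; the depth used when the grid is written to disk.
    name : str
        Free-text label carried through the pipeline for provenance.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    bit_depth: int = 16
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"data must be a 3D (z, y, x) array, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.data.size and float(np.min(self.data)) < 0:
            raise ValidationError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in nm^3."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def positions(self, axis: str) -> np.ndarray:
        """Physical coordinates (nm) of voxel centres along ``axis``."""
        a = _axis_index(axis)
        return np.arange(self.shape[a], dtype=float) * self.spacing[a]

    def with_data(self, data: np.ndarray, name: str | None = None) -> "VoxelGrid":
        return replace(self, data=data, name=self.name if name is None else name)


def _axis_index(axis: str) -> int:
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    return AXES[axis]


def read_stack(path, spacing, name: str = "") -> VoxelGrid:
    """Read a single- or multi-page grayscale TIFF into a :class:`VoxelGrid`.

    ``spacing`` is ``(dz, dy, dx)`` in nm and always wins over any
    resolution tags found in the file (a warning is emitted on conflict).
    """
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive values, got {spacing}")
    with tifffile.TiffFile(str(path)) as tif:
        if tif.pages[0].samplesperpixel > 1:
            raise StackFormatError(f"{path}: RGB/multichannel TIFF not supported")
        arr = tif.asarray()
        _warn_on_tag_conflict(tif, spacing)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise StackFormatError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise StackFormatError(f"{path}: unsupported dtype {arr.dtype}; need uint8/uint16")
    return VoxelGrid(arr, spacing, bit_depth=depth, name=name or str(path))


def _warn_on_tag_conflict(tif, spacing) -> None:
    """Best-effort check of TIFF XResolution against the supplied pixel size."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None or unit is None:
            return
        num, den = xres.value
        if num == 0 or den == 0:
            return
        per_unit = num / den  # pixels per unit
        unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit.value, "value", unit.value))
        if unit_nm is None:
            return
        tag_dx = unit_nm / per_unit
        if abs(tag_dx - spacing[2]) / spacing[2] > 0.05:
            warnings.warn(
                f"TIFF resolution tag implies dx={tag_dx:.1f} nm but config says "
                f"{spacing[2]:.1f} nm; using the configured spacing",
                stacklevel=3,
            )
    except Exception:  # tag dialects vary; never fail a read over metadata
        return


def write_stack(grid: VoxelGrid, path) -> None:
    """Write a grid as a multi-page grayscale TIFF at its declared bit depth.

    Integer-valued data within range is written bit-exactly.  Float data is
    linearly rescaled from ``[0, max]`` to the full integer range and
    rounded, so the quantization error never exceeds half a step of
    ``max / (2**bit_depth - 1)``.
    """
    maxval = 2**grid.bit_depth - 1
    dtype = np.uint8 if grid.bit_depth == 8 else np.uint16
    data = grid.data
    if np.issubdtype(data.dtype, np.integer) and data.max(initial=0) <= maxval:
        out = data.astype(dtype)
    else:
        peak = float(data.max()) if data.size else 0.0
        if peak <= 0:
            out = np.zeros(data.shape, dtype)
        elif float(data.min()) >= 0 and np.allclose(data, np.round(data)) and peak <= maxval:
            out = np.round(data).astype(dtype)
        else:
            out = np.round(np.asarray(data, float) * (maxval / peak)).astype(dtype)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def max_projection(grid: VoxelGrid, axis: str = "z"):
    """Maximum-intensity projection along one axis.

    Returns ``(image, pixel_spacing)`` where ``pixel_spacing`` is the
    spacing of the two remaining axes in array order.
    """
    a = _axis_index(axis)
    img = grid.data.max(axis=a)
    sp = tuple(s for i, s in enumerate(grid.spacing) if i != a)
    return img, sp


#: view name -> (axis permutation applied to (z, y, x) data, description)
_RESLICE_PERMS = {
    "xz": (1, 0, 2),  # planes indexed by y; each plane is a (z, x) view
    "yz": (2, 0, 1),  # planes indexed by x; each plane is a (z, y) view
}


def reslice(grid: VoxelGrid, view: str) -> VoxelGrid:
    """Permute axes so the requested orthogonal plane becomes the in-plane view.

    No interpolation is performed: the voxel multiset is untouched and the
    (generally anisotropic) spacing is permuted along with the axes.
    Reslicing to ``xz`` twice is the identity.
    """
    if view not in _RESLICE_PERMS:
        raise ValidationError(f"view must be one of {sorted(_RESLICE_PERMS)}, got {view!r}")
    perm = _RESLICE_PERMS[view]
    data = np.ascontiguousarray(np.transpose(grid.data, perm))
    spacing = tuple(grid.spacing[p] for p in perm)
    return VoxelGrid(data, spacing, bit_depth=grid.bit_depth, name=f"{grid.name}|{view}")


def to_8bit(grid: VoxelGrid) -> VoxelGrid:
    """Linearly rescale ``[0, max]`` to ``[0, 255]`` and quantize to uint8."""
    peak = float(grid.data.max()) if grid.data.size else 0.0
    if peak <= 0:
        data = np.zeros(grid.shape, np.uint8)
    else:
        data = np.round(np.asarray(grid.data, float) * (255.0 / peak)).astype(np.uint8)
    return VoxelGrid(data, grid.spacing, bit_depth=8, name=grid.name)
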