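"""Volume and ROI containers plus TIFF/NRRD readers and writers.

Axis convention throughout the package is ``(depth, row, col)``; voxel sizes
are micrometres per axis in the same order. Multi-page TIFF stores one page
per depth slice; NRRD stores spacings as authoritative voxel-size metadata.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from . import _nrrd
from .errors import FormatError, InputError, ValidationError

log = logging.getLogger(__name__)

GRAYSCALE = "grayscale"
BINARY_MASK = "binary_mask"


@dataclass
class Volume3D:
    """A 3-D scalar lattice with physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(depth, row, col)``.
    voxel_size_um
        Strictly positive per-axis voxel size in micrometres.
    intensity_kind
        ``"grayscale"`` or ``"binary_mask"``; masks may only contain {0, 1}.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_kind: str = GRAYSCALE

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected 3-D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel sizes must be three positive reals, got {self.voxel_size_um}")
        self.voxel_size_um = vs
        if self.intensity_kind not in (GRAYSCALE, BINARY_MASK):
            raise ValidationError(f"unknown intensity_kind {self.intensity_kind!r}")
        if self.intensity_kind == BINARY_MASK:
            uniq = np.unique(self.data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError("binary_mask volume contains values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis in micrometres."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size_um))


@dataclass
class ROIBox:
    """An axis-aligned box of voxels, 0-based and half-open per axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    label: str = ""

    def __post_init__(self):
        self.lo = tuple(int(v) for v in self.lo)
        self.hi = tuple(int(v) for v in self.hi)
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValidationError("ROI lo/hi must be integer triples")
        for axis, (a, b) in enumerate(zip(self.lo, self.hi)):
            if a < 0 or a >= b:
                raise ValidationError(f"ROI {self.label!r}: need 0 <= lo < hi on axis {axis}, got [{a}, {b})")

    def check_within(self, shape) -> None:
        for axis, (b, n) in enumerate(zip(self.hi, shape)):
            if b > n:
                raise ValidationError(f"ROI {self.label!r} exceeds volume extent {shape} on axis {axis}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))

    @property
    def n_voxels(self) -> int:
        return int(np.prod([b - a for a, b in zip(self.lo, self.hi)]))


_TIFF_EXT = (".tif", ".tiff")
_NRRD_EXT = (".nrrd",)


def _coerce_mask(data: np.ndarray) -> np.ndarray:
    """Coerce any nonzero value to 1, warning when values other than {0,1} occur."""
    if not np.isin(np.unique(data), (0, 1)).all():
        log.warning("mask contains values outside {0, 1}; coercing nonzero to 1")
    return (data != 0).astype(np.uint8)


def read_volume(path, voxel_size_um=None, intensity_kind: str = GRAYSCALE) -> Volume3D:
    """Read a multi-page TIFF or NRRD volume.

    An explicit ``voxel_size_um`` overrides any file metadata. TIFF carries
    no reliable spacing, so without an override the voxel size defaults to
    (1, 1, 1) µm with a logged warning.
    """
    if not os.path.isfile(path):
        raise InputError(f"no such file: {path}")
    ext = os.path.splitext(str(path))[1].lower()
    meta_spacing = None
    if ext in _TIFF_EXT:
        try:
            with tifffile.TiffFile(path) as tif:
                shapes = {page.shape for page in tif.pages}
                if len(shapes) != 1:
                    raise FormatError(f"{path}: TIFF pages have inconsistent shapes {sorted(shapes)}")
                data = tif.asarray()
        except tifffile.TiffFileError as exc:
            raise FormatError(f"{path}: cannot read TIFF stack ({exc})") from exc
        if data.dtype == object or data.ndim not in (2, 3):
            raise FormatError(f"{path}: TIFF pages do not form a uniform 3-D stack")
        if data.ndim == 2:
            data = data[None]
    elif ext in _NRRD_EXT:
        data, header = _nrrd.read_nrrd(path)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D NRRD, got dimension {data.ndim}")
        meta_spacing = _nrrd.parse_spacings(header)
    else:
        raise FormatError(f"{path}: unsupported extension {ext!r} (use .tif/.tiff/.nrrd)")

    if voxel_size_um is not None:
        vs = tuple(float(v) for v in voxel_size_um)
    elif meta_spacing is not None:
        vs = meta_spacing
    else:
        log.warning("%s: no voxel-size metadata and no override; defaulting to (1, 1, 1) um", path)
        vs = (1.0, 1.0, 1.0)
    if any(v <= 0 for v in vs) or len(vs) != 3:
        raise ValidationError(f"{path}: voxel size must be three positive reals, got {vs}")

    if intensity_kind == BINARY_MASK:
        data = _coerce_mask(data)
    return Volume3D(data, vs, intensity_kind)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as a multi-page TIFF or NRRD, chosen by extension."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise InputError(f"parent directory does not exist: {parent}")
    ext = os.path.splitext(str(path))[1].lower()
    data = vol.data
    if vol.intensity_kind == BINARY_MASK:
        data = data.astype(np.uint8)
    if ext in _TIFF_EXT:
        tifffile.imwrite(path, data)
    elif ext in _NRRD_EXT:
        _nrrd.write_nrrd(path, data, spacings=vol.voxel_size_um)
    else:
        raise FormatError(f"{path}: unsupported extension {ext!r} (use .tif/.tiff/.nrrd)")


def orthogonal_slices(vol: Volume3D, index) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract the axial, coronal and sagittal planes through ``index``.

    Pure lattice indexing — no resampling. ``index`` is a (depth, row, col)
    triple of 0-based positions.
    """
    idx = tuple(int(v) for v in index)
    if len(idx) != 3:
        raise ValidationError("index must be a triple of slice positions")
    for axis, (i, n) in enumerate(zip(idx, vol.shape)):
        if not 0 <= i < n:
            raise ValidationError(f"slice index {i} out of bounds [0, {n}) on axis {axis}")
    axial = vol.data[idx[0], :, :]
    coronal = vol.data[:, idx[1], :]
    sagittal = vol.data[:, :, idx[2]]
    return axial, coronal, sagittal
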