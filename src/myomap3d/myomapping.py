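"""Wall-frame construction and helical/intrusion-angle mapping.

A :class:`WallFrame` carries a per-voxel orthonormal right-handed triad
(circumferential ``c``, longitudinal ``l``, radial ``r``) and a normalised
transmural depth (0 = epicardium, 1 = endocardium). Fiber directions are
axial, so each vector is sign-normalised (``v . c >= 0``) before angles are
taken and all profile statistics use angle doubling.

Angle conventions
-----------------
* Helical angle HA = atan2(v.l, v.c) in degrees, range (-90, 90].
* Intrusion angle IA: by default the elevation of the fiber out of the
  tangential (c, l) plane — 0 for in-plane fibers, +/-90 for radial fibers.
  The literal to-radial angle is available as ``ia_convention="to_radial"``
  (= 90 - |elevation|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .structure_tensor import (
    OrientationField,
    compute_structure_tensor,
    eigendecompose_field,
    fiber_directions,
    fractional_anisotropy,
)
from .volume_io import BINARY_MASK, ROIBox, Volume3D

SLAB_AXES = "slab_axes"
SURFACE_NORMAL = "surface_normal"

IA_CONVENTIONS = ("elevation", "to_radial")


@dataclass
class WallFrame:
    """Per-voxel local wall coordinate frame.

    ``c``, ``l``, ``r`` have shape broadcastable to ``shape + (3,)`` and
    satisfy |c| = |l| = |r| = 1, pairwise orthogonal, c x l = r. ``depth``
    is the normalised transmural coordinate, NaN outside tissue.
    """

    c: np.ndarray
    l: np.ndarray
    r: np.ndarray
    depth: np.ndarray
    mode: str = SLAB_AXES
    tissue: np.ndarray | None = None

    @property
    def shape(self):
        return self.depth.shape


@dataclass
class MyoMap:
    """Co-registered HA/IA/FA volumes with a shared validity mask.

    Invalid voxels carry NaN and are excluded from all statistics.
    """

    HA: np.ndarray
    IA: np.ndarray
    FA: np.ndarray
    valid: np.ndarray
    depth: np.ndarray | None = None


@dataclass
class TransmuralProfile:
    """Axial angle statistics binned by transmural depth."""

    bin_centers: np.ndarray
    mean_angle: np.ndarray  # degrees; NaN for empty bins
    dispersion: np.ndarray  # degrees; NaN for empty bins
    n: np.ndarray
    empty: np.ndarray


def default_tissue_mask(vol: Volume3D, smooth_sigma_vox: float = 1.0) -> Volume3D:
    """Otsu threshold on the smoothed volume, then the largest connected component."""
    data = ndimage.gaussian_filter(vol.data.astype(np.float64), smooth_sigma_vox, mode="nearest")
    thr = threshold_otsu(data)
    fg = data > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValidationError("Otsu tissue mask is empty")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == np.argmax(counts)
    return Volume3D(mask.astype(np.uint8), vol.voxel_size_um, BINARY_MASK)


def _unit(axis: int) -> np.ndarray:
    e = np.zeros(3)
    e[axis] = 1.0
    return e


def slab_frame_axes(radial_axis: int = 0, longitudinal_axis: int = 1, flip_radial: bool = False):
    """Constant (c, l, r) triad for a slab sample along lattice axes.

    ``r`` points from the epicardial face to the endocardial face along
    ``radial_axis`` (flip with ``flip_radial``); ``c = l x r`` fixes
    right-handedness (c x l = r).
    """
    if radial_axis == longitudinal_axis or not (0 <= radial_axis < 3 and 0 <= longitudinal_axis < 3):
        raise ValidationError("radial_axis and longitudinal_axis must be distinct axes in {0,1,2}")
    r = -_unit(radial_axis) if flip_radial else _unit(radial_axis)
    l = _unit(longitudinal_axis)
    c = np.cross(l, r)
    return c, l, r


def _slab_depth(tissue: np.ndarray, radial_axis: int, flip_radial: bool) -> np.ndarray:
    """Per-column normalised depth between first and last tissue voxel."""
    t = np.moveaxis(tissue, radial_axis, 0)
    n = t.shape[0]
    any_col = t.any(axis=0)
    first = np.argmax(t, axis=0)
    last = n - 1 - np.argmax(t[::-1], axis=0)
    span = np.maximum(last - first, 1)
    idx = np.arange(n).reshape((n,) + (1,) * (t.ndim - 1))
    depth = (idx - first) / span
    depth = np.clip(depth, 0.0, 1.0)
    if flip_radial:
        depth = 1.0 - depth
    depth = np.where(t, depth, np.nan)
    depth = np.where(any_col, depth, np.nan)
    return np.moveaxis(depth, 0, radial_axis)


def fit_wall_frame(
    tissue_mask: Volume3D,
    mode: str = SLAB_AXES,
    radial_axis: int = 0,
    longitudinal_axis: int = 1,
    flip_radial: bool = False,
    epi_mask: np.ndarray | None = None,
    endo_mask: np.ndarray | None = None,
    long_axis_hint=(0.0, 1.0, 0.0),
) -> WallFrame:
    """Build a per-voxel wall frame from a binary tissue mask.

    ``slab_axes`` (default): the triad is constant along lattice axes and
    depth is measured per transmural column between the first and last
    tissue voxel, so warped slab surfaces do not bias depth binning.

    ``surface_normal``: ``r`` is the normalised gradient of the Euclidean
    distance to the labelled epicardial surface, depth is
    ``d_epi / (d_epi + d_endo)``, ``l`` is the projection of
    ``long_axis_hint`` onto the plane perpendicular to ``r`` and ``c``
    completes the right-handed triad.
    """
    tissue = tissue_mask.data.astype(bool)
    if not tissue.any():
        raise ValidationError("tissue mask is empty")

    if mode == SLAB_AXES:
        c, l, r = slab_frame_axes(radial_axis, longitudinal_axis, flip_radial)
        depth = _slab_depth(tissue, radial_axis, flip_radial)
        shape = tissue.shape
        return WallFrame(
            c=np.broadcast_to(c, shape + (3,)),
            l=np.broadcast_to(l, shape + (3,)),
            r=np.broadcast_to(r, shape + (3,)),
            depth=depth,
            mode=mode,
            tissue=tissue,
        )

    if mode == SURFACE_NORMAL:
        if epi_mask is None or endo_mask is None:
            raise ValidationError("surface_normal mode requires labelled epi and endo face masks")
        spacing = tissue_mask.voxel_size_um
        d_epi = ndimage.distance_transform_edt(~epi_mask.astype(bool), sampling=spacing)
        d_endo = ndimage.distance_transform_edt(~endo_mask.astype(bool), sampling=spacing)
        total = d_epi + d_endo
        depth = np.where(tissue & (total > 0), d_epi / np.where(total > 0, total, 1.0), np.nan)
        grads = np.gradient(ndimage.gaussian_filter(d_epi, 1.0, mode="nearest"), *spacing)
        r_vec = np.stack(grads, axis=-1)
        norm = np.linalg.norm(r_vec, axis=-1, keepdims=True)
        r_vec = np.divide(r_vec, norm, out=np.zeros_like(r_vec), where=norm > 1e-12)
        hint = np.asarray(long_axis_hint, dtype=float)
        hint = hint / np.linalg.norm(hint)
        l_vec = hint - np.sum(r_vec * hint, axis=-1, keepdims=True) * r_vec
        ln = np.linalg.norm(l_vec, axis=-1, keepdims=True)
        # where the hint is (anti)parallel to r, fall back to any perpendicular
        alt = np.cross(r_vec, np.array([1.0, 0.0, 0.0]))
        alt_n = np.linalg.norm(alt, axis=-1, keepdims=True)
        alt = np.where(alt_n < 1e-8, np.cross(r_vec, np.array([0.0, 0.0, 1.0])), alt)
        alt = alt / np.maximum(np.linalg.norm(alt, axis=-1, keepdims=True), 1e-300)
        l_vec = np.where(ln < 1e-8, alt, l_vec / np.where(ln < 1e-8, 1.0, ln))
        c_vec = np.cross(l_vec, r_vec)
        return WallFrame(c=c_vec, l=l_vec, r=r_vec, depth=depth, mode=mode, tissue=tissue)

    raise ValidationError(f"unknown wall-frame mode {mode!r}")


def _check_lattice(fibers: OrientationField, frame: WallFrame) -> None:
    if fibers.shape != frame.shape:
        raise ValidationError(f"fiber field shape {fibers.shape} != frame shape {frame.shape}")


def sign_normalize(vectors: np.ndarray, frame: WallFrame) -> np.ndarray:
    """Flip each axial vector so v.c >= 0 (ties: v.l >= 0, then v.r >= 0)."""
    vc = np.sum(vectors * frame.c, axis=-1)
    vl = np.sum(vectors * frame.l, axis=-1)
    vr = np.sum(vectors * frame.r, axis=-1)
    flip = (vc < 0) | ((vc == 0) & (vl < 0)) | ((vc == 0) & (vl == 0) & (vr < 0))
    return np.where(flip[..., None], -vectors, vectors)


def helical_angle(fibers: OrientationField, frame: WallFrame) -> tuple[np.ndarray, np.ndarray]:
    """Helical angle in degrees, range (-90, 90], plus its validity mask.

    Voxels whose fiber is almost purely radial (tangential magnitude below
    1e-6) have no defined helix and are marked invalid.
    """
    _check_lattice(fibers, frame)
    v = sign_normalize(fibers.vectors, frame)
    vc = np.sum(v * frame.c, axis=-1)
    vl = np.sum(v * frame.l, axis=-1)
    tangential = np.hypot(vc, vl)
    ha = np.degrees(np.arctan2(vl, vc))
    ha = np.where(ha <= -90.0, ha + 180.0, ha)  # fold -90 onto +90
    valid = fibers.valid & (tangential >= 1e-6)
    ha = np.where(valid, ha, np.nan)
    return ha, valid


def intrusion_angle(
    fibers: OrientationField, frame: WallFrame, convention: str = "elevation"
) -> tuple[np.ndarray, np.ndarray]:
    """Intrusion angle in degrees plus its validity mask.

    ``elevation`` (default): arcsin(v.r) after sign normalisation — 0 for
    fibers in the tangential plane, +90 for the radial direction.
    ``to_radial``: 90 - |elevation| (the literal angle to the radial axis).
    """
    if convention not in IA_CONVENTIONS:
        raise ValidationError(f"ia_convention must be one of {IA_CONVENTIONS}")
    _check_lattice(fibers, frame)
    v = sign_normalize(fibers.vectors, frame)
    vr = np.sum(v * frame.r, axis=-1)
    ia = np.degrees(np.arcsin(np.clip(vr, -1.0, 1.0)))
    if convention == "to_radial":
        ia = 90.0 - np.abs(ia)
    ia = np.where(fibers.valid, ia, np.nan)
    return ia, fibers.valid.copy()


def axial_mean_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    """Axial mean and dispersion (degrees) of 180-degree-periodic angles.

    Uses angle doubling: mean = 0.5 * atan2(sum sin 2t, sum cos 2t);
    dispersion = 0.5 * circular standard deviation of 2t.
    """
    t2 = np.radians(angles_deg) * 2.0
    s, c = np.sin(t2).sum(), np.cos(t2).sum()
    n = angles_deg.size
    if n == 0:
        return float("nan"), float("nan")
    mean = 0.5 * np.degrees(np.arctan2(s, c))
    rbar = min(np.hypot(s, c) / n, 1.0)
    disp = 0.5 * np.degrees(np.sqrt(max(-2.0 * np.log(max(rbar, 1e-300)), 0.0)))
    return float(mean), float(disp)


def transmural_profile(
    angle_deg: np.ndarray,
    frame: WallFrame,
    n_bins: int,
    valid: np.ndarray | None = None,
) -> TransmuralProfile:
    """Bin valid voxels by depth and compute per-bin axial statistics.

    Bins are equal-width over [0, 1]; bins with no voxels are marked empty
    (NaN mean), never reported as zero.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    ok = np.isfinite(angle_deg) & np.isfinite(frame.depth)
    if valid is not None:
        ok &= valid
    if not ok.any():
        raise ValidationError("no valid voxels to profile")
    depth = frame.depth[ok]
    ang = angle_deg[ok]
    bins = np.clip((depth * n_bins).astype(int), 0, n_bins - 1)

    centers = (np.arange(n_bins) + 0.5) / n_bins
    mean = np.full(n_bins, np.nan)
    disp = np.full(n_bins, np.nan)
    counts = np.bincount(bins, minlength=n_bins)
    for b in np.nonzero(counts)[0]:
        mean[b], disp[b] = axial_mean_deg(ang[bins == b])
    return TransmuralProfile(
        bin_centers=centers,
        mean_angle=mean,
        dispersion=disp,
        n=counts,
        empty=counts == 0,
    )


def mean_fa(fa_field: np.ndarray, region, valid: np.ndarray | None = None) -> tuple[float, int]:
    """Arithmetic mean of FA over valid voxels in an ROI box or boolean mask.

    Returns ``(mean, n_voxels)``; an empty overlap is an error.
    """
    if isinstance(region, ROIBox):
        region.check_within(fa_field.shape)
        sel = np.zeros(fa_field.shape, dtype=bool)
        sel[region.slices()] = True
    else:
        sel = np.asarray(region).astype(bool)
        if sel.shape != fa_field.shape:
            raise ValidationError("region mask shape does not match FA field")
    ok = sel & np.isfinite(fa_field)
    if valid is not None:
        ok &= valid
    n = int(ok.sum())
    if n == 0:
        raise ValidationError("region overlaps no valid voxels")
    return float(fa_field[ok].mean()), n


def compute_myomap(
    vol: Volume3D,
    frame: WallFrame | None = None,
    tissue_mask: Volume3D | None = None,
    gradient_scale_um: float | None = None,
    window_size_um: float = 123.5,
    window_kind: str = "fwhm",
    ia_convention: str = "elevation",
    eps: float = 1e-6,
    radial_axis: int = 0,
    longitudinal_axis: int = 1,
) -> MyoMap:
    """End-to-end myomapping: tensor -> eigensystem -> HA/IA/FA volumes.

    Validity combines tissue membership, non-degeneracy, the boundary margin
    of one integration-window width, and angle-specific exclusions; invalid
    voxels carry NaN.
    """
    if tissue_mask is None:
        tissue_mask = default_tissue_mask(vol)
    if frame is None:
        frame = fit_wall_frame(tissue_mask, SLAB_AXES, radial_axis, longitudinal_axis)
    tf = compute_structure_tensor(vol, gradient_scale_um, window_size_um, window_kind)
    eig = eigendecompose_field(tf, eps=eps)
    fa = fractional_anisotropy(eig)
    fibers = fiber_directions(eig)

    base_valid = fibers.valid & tissue_mask.data.astype(bool) & tf.interior_mask() & np.isfinite(frame.depth)
    fibers_masked = OrientationField(fibers.vectors, base_valid, tf.boundary_margin_vox)
    ha, ha_valid = helical_angle(fibers_masked, frame)
    ia, ia_valid = intrusion_angle(fibers_masked, frame, ia_convention)
    fa = np.where(base_valid, fa, np.nan)
    return MyoMap(HA=ha, IA=ia, FA=fa, valid=base_valid, depth=frame.depth)
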