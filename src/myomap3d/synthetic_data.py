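"""Phantoms with known ground truth for validating every pipeline stage.

Fiber phantoms are slabs of soft-profile tubes (Gaussian cross-section)
laid along a depth-dependent direction: the helical angle ramps linearly
from the epicardial to the endocardial face while the intrusion angle stays
constant. Tube texture (rather than plane-wave gratings) makes the
structure tensor's smallest-eigenvalue direction unique along the fiber.

Collagen phantoms are binary masks hitting a requested volume fraction
exactly (to within one voxel) by thresholding a geometry-shaped propensity
field at the matching count.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, ValidationError
from .myomapping import slab_frame_axes
from .structure_tensor import OrientationField
from .volume_io import BINARY_MASK, GRAYSCALE, Volume3D, write_volume


@dataclass
class FiberPhantomSpec:
    """Parameters of a helical-ramp fiber slab.

    Depth runs along axis 0 (the radial axis); HA ramps linearly from
    ``ha_epi_deg`` at depth 0 to ``ha_endo_deg`` at depth 1. ``tube_density``
    is tubes per 100 square voxels of cross-section. ``dispersion_deg`` adds
    Gaussian angular jitter per tube; ``disorganised_range`` (a depth
    interval) makes tube directions isotropic there, emulating a trabecular
    zone, and invalidates the ground truth inside it.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: tuple[float, float, float] = (5.8, 5.8, 5.8)
    ha_epi_deg: float = 60.0
    ha_endo_deg: float = -60.0
    ia_deg: float = 0.0
    tube_radius_vox: float = 2.0
    tube_density: float = 6.0
    dispersion_deg: float = 0.0
    noise_sigma: float = 0.0
    ring_amplitude: float = 0.0
    ring_period_vox: float = 8.0
    contrast: float = 1.0
    disorganised_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.dims) != 3 or min(self.dims) < 4:
            raise ValidationError(f"dims must be a triple >= 4, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValidationError("voxel sizes must be positive")
        for name in ("ha_epi_deg", "ha_endo_deg"):
            v = getattr(self, name)
            if not -90.0 < v <= 90.0:
                raise ValidationError(f"{name}={v} outside (-90, 90]")
        if self.tube_density <= 0:
            raise ValidationError("tube_density must be > 0")
        if self.tube_radius_vox <= 0:
            raise ValidationError("tube_radius_vox must be > 0")
        if self.dispersion_deg < 0 or self.noise_sigma < 0 or self.ring_amplitude < 0:
            raise ValidationError("dispersion/noise/ring amplitudes must be nonnegative")
        if self.disorganised_range is not None:
            a, b = self.disorganised_range
            if not 0.0 <= a < b <= 1.0:
                raise ValidationError("disorganised_range must be a sub-interval of [0, 1]")


@dataclass
class CollagenPhantomSpec:
    """Parameters of a binary collagen mask with a known volume fraction."""

    dims: tuple[int, int, int] = (128, 128, 128)
    target_fraction: float = 0.1
    geometry: str = "diffuse_streaks"
    streak_radius_vox: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or min(self.dims) < 2:
            raise ValidationError(f"dims must be a triple >= 2, got {self.dims}")
        if not 0.0 < self.target_fraction < 1.0:
            raise ValidationError("target_fraction must be in (0, 1)")
        if self.geometry not in ("diffuse_streaks", "compact_patch", "mixed"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")
        if self.streak_radius_vox <= 0:
            raise ValidationError("streak_radius_vox must be > 0")


def _direction_at_depth(spec: FiberPhantomSpec, d: float) -> np.ndarray:
    c, l, r = slab_frame_axes(radial_axis=0, longitudinal_axis=1)
    ha = np.radians(spec.ha_epi_deg + (spec.ha_endo_deg - spec.ha_epi_deg) * d)
    ia = np.radians(spec.ia_deg)
    return np.cos(ia) * (np.cos(ha) * c + np.sin(ha) * l) + np.sin(ia) * r


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p1 = np.cross(u, helper)
    p1 /= np.linalg.norm(p1)
    return p1, np.cross(u, p1)


def _add_tube(acc: np.ndarray, p: np.ndarray, u: np.ndarray, radius: float, contrast: float) -> None:
    """Accumulate a Gaussian-profile tube (infinite line, clipped) into ``acc``.

    Rendered segment-by-segment along the line parameter so tilted tubes do
    not force a whole-volume bounding box; each voxel is gated by its line
    projection, so segments partition contributions without double counting.
    """
    dims = np.array(acc.shape)
    pad = max(3.5 * radius, 2.0)
    tmin, tmax = -np.inf, np.inf
    for i in range(3):
        if abs(u[i]) > 1e-9:
            t1 = (-pad - p[i]) / u[i]
            t2 = (dims[i] - 1 + pad - p[i]) / u[i]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
        elif p[i] < -pad or p[i] > dims[i] - 1 + pad:
            return
    if not np.isfinite(tmin) or tmax <= tmin:
        return
    seg_len = max(8.0 * radius, 16.0)
    n_seg = max(1, int(np.ceil((tmax - tmin) / seg_len)))
    edges = np.linspace(tmin, tmax, n_seg + 1)
    inv2r2 = 1.0 / (2.0 * radius * radius)
    for si in range(n_seg):
        ta, tb = edges[si], edges[si + 1]
        a = p + ta * u
        b = p + tb * u
        lo = np.maximum(np.floor(np.minimum(a, b) - pad).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(a, b) + pad).astype(int) + 1, dims)
        if (hi <= lo).any():
            continue
        z = (np.arange(lo[0], hi[0], dtype=np.float64) - p[0])[:, None, None]
        y = (np.arange(lo[1], hi[1], dtype=np.float64) - p[1])[None, :, None]
        x = (np.arange(lo[2], hi[2], dtype=np.float64) - p[2])[None, None, :]
        proj = z * u[0] + y * u[1] + x * u[2]
        d2 = z * z + y * y + x * x - proj * proj
        gate = (proj >= ta) & (proj < tb) if si < n_seg - 1 else (proj >= ta) & (proj <= tb)
        gate &= d2 < pad * pad
        if not gate.any():
            continue
        block = acc[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        block[gate] += contrast * np.exp(-d2[gate] * inv2r2)


def generate_fiber_phantom(spec: FiberPhantomSpec):
    """Generate a fiber slab, its jitter-free ground-truth orientation and depth.

    Returns ``(Volume3D, OrientationField, depth)`` where depth is the
    per-voxel normalised transmural coordinate (linear in slice index).
    Deterministic for a fixed seed.
    """
    Z, Y, X = spec.dims
    ss = np.random.SeedSequence(spec.seed)
    ss_tubes, ss_art = ss.spawn(2)
    rng = np.random.default_rng(ss_tubes)

    depth_axis = np.arange(Z, dtype=np.float64) / max(Z - 1, 1)
    depth = np.broadcast_to(depth_axis[:, None, None], spec.dims).copy()

    # jitter-free ground truth, one direction per slice
    truth = np.empty(spec.dims + (3,), dtype=np.float64)
    truth_valid = np.ones(spec.dims, dtype=bool)
    for z in range(Z):
        truth[z] = _direction_at_depth(spec, depth_axis[z])
    if spec.disorganised_range is not None:
        a, b = spec.disorganised_range
        zone = (depth_axis >= a) & (depth_axis <= b)
        truth[zone] = 0.0
        truth_valid[zone] = False

    acc = np.zeros(spec.dims, dtype=np.float64)
    n_tubes = max(1, int(round(spec.tube_density / 100.0 * Z * max(Y, X))))
    disp_rad = np.radians(spec.dispersion_deg)
    for _ in range(n_tubes):
        z0 = rng.uniform(0, Z - 1)
        p = np.array([z0, rng.uniform(0, Y - 1), rng.uniform(0, X - 1)])
        d0 = z0 / max(Z - 1, 1)
        in_zone = (
            spec.disorganised_range is not None
            and spec.disorganised_range[0] <= d0 <= spec.disorganised_range[1]
        )
        if in_zone:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
        else:
            u = _direction_at_depth(spec, d0)
            if disp_rad > 0:
                theta = rng.normal(0.0, disp_rad)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                p1, p2 = _perp_basis(u)
                u = np.cos(theta) * u + np.sin(theta) * (np.cos(phi) * p1 + np.sin(phi) * p2)
                u /= np.linalg.norm(u)
        _add_tube(acc, p, u, spec.tube_radius_vox, spec.contrast)

    vol = Volume3D(acc, spec.voxel_size_um, GRAYSCALE)
    if spec.noise_sigma > 0 or spec.ring_amplitude > 0:
        vol = add_artefacts(
            vol,
            spec.noise_sigma,
            spec.ring_amplitude,
            ring_axis=0,
            ring_period_vox=spec.ring_period_vox,
            seed=int(ss_art.generate_state(1)[0]),
        )
    field = OrientationField(vectors=truth, valid=truth_valid)
    return vol, field, depth


def _streak_field(dims, radius: float, n_streaks: int, rng) -> np.ndarray:
    field = np.zeros(dims, dtype=np.float64)
    for _ in range(n_streaks):
        p = np.array([rng.uniform(0, d - 1) for d in dims])
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        _add_tube(field, p, u, radius, 1.0)
    return field


def _patch_field(dims, rng) -> np.ndarray:
    center = np.array(dims, dtype=float) / 2.0 + rng.uniform(-2, 2, size=3)
    semi = rng.uniform(0.6, 1.4, size=3)
    z = ((np.arange(dims[0]) - center[0]) / semi[0])[:, None, None]
    y = ((np.arange(dims[1]) - center[1]) / semi[1])[None, :, None]
    x = ((np.arange(dims[2]) - center[2]) / semi[2])[None, None, :]
    return -(z * z + y * y + x * x)  # larger = closer to center


def _top_k_mask(field: np.ndarray, k: int, forbidden: np.ndarray | None = None) -> np.ndarray:
    flat = field.ravel().copy()
    if forbidden is not None:
        flat[forbidden.ravel()] = -np.inf
    idx = np.argpartition(flat, flat.size - k)[flat.size - k :]
    mask = np.zeros(flat.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(field.shape)


def generate_collagen_phantom(spec: CollagenPhantomSpec):
    """Generate a binary collagen mask hitting ``target_fraction`` exactly.

    The requested fraction is converted to a voxel count and the propensity
    field of the chosen geometry is thresholded at exactly that count, so
    ``achieved_fraction`` differs from the target by at most half a voxel.
    Streak geometries retry with more streaks (bounded) if the field cannot
    support the count.
    """
    N = int(np.prod(spec.dims))
    k = int(round(spec.target_fraction * N))
    if k < 1:
        raise GenerationError(f"target_fraction {spec.target_fraction} yields zero voxels at {spec.dims}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    if spec.geometry == "compact_patch":
        mask = _top_k_mask(_patch_field(spec.dims, rng), k)
    else:
        # voxels per streak ~ length x cross-section at the e^-1/2 radius
        per_streak = max(np.mean(spec.dims) * np.pi * (2.0 * spec.streak_radius_vox) ** 2, 8.0)
        k_streaks = k if spec.geometry == "diffuse_streaks" else k - k // 2
        n_streaks = max(8, int(np.ceil(2.0 * k_streaks / per_streak)))
        patch_mask = None
        if spec.geometry == "mixed":
            patch_mask = _top_k_mask(_patch_field(spec.dims, rng), k // 2)
        field = _streak_field(spec.dims, spec.streak_radius_vox, n_streaks, rng)
        for _attempt in range(6):
            supported = int((field > 1e-9).sum())
            if patch_mask is not None:
                supported = int(((field > 1e-9) & ~patch_mask).sum())
            if supported >= k_streaks:
                break
            extra = _streak_field(spec.dims, spec.streak_radius_vox, n_streaks, rng)
            field += extra
            n_streaks *= 2
        else:
            raise GenerationError("could not reach target fraction with streak geometry")
        if patch_mask is not None:
            mask = patch_mask | _top_k_mask(field, k_streaks, forbidden=patch_mask)
        else:
            mask = _top_k_mask(field, k_streaks)

    achieved = float(mask.sum()) / N
    vol = Volume3D(mask.astype(np.uint8), (1.0, 1.0, 1.0), BINARY_MASK)
    if abs(achieved - spec.target_fraction) > 0.005:
        raise GenerationError(
            f"achieved fraction {achieved:.4f} misses target {spec.target_fraction:.4f}"
        )
    return vol, achieved


def add_artefacts(
    vol: Volume3D,
    noise_sigma: float = 0.0,
    ring_amplitude: float = 0.0,
    ring_axis: int = 0,
    ring_period_vox: float = 8.0,
    seed: int = 0,
) -> Volume3D:
    """Add white Gaussian noise and concentric sinusoidal ring modulation.

    Rings are constant on circles about the lattice center in the planes
    perpendicular to ``ring_axis``, with amplitude ``ring_amplitude``,
    period ``ring_period_vox`` and a random phase drawn from ``seed``.
    Zero amplitudes return an identical copy.
    """
    if noise_sigma < 0 or ring_amplitude < 0:
        raise ValidationError("noise_sigma and ring_amplitude must be nonnegative")
    if ring_period_vox <= 0:
        raise ValidationError("ring_period_vox must be positive")
    if ring_axis not in (0, 1, 2):
        raise ValidationError("ring_axis must be 0, 1 or 2")
    data = vol.data.astype(np.float64).copy()
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    if ring_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        axes = [i for i in range(3) if i != ring_axis]
        coords = []
        for i in axes:
            c = np.arange(data.shape[i], dtype=np.float64) - (data.shape[i] - 1) / 2.0
            shape = [1, 1, 1]
            shape[i] = data.shape[i]
            coords.append(c.reshape(shape))
        radius = np.sqrt(coords[0] ** 2 + coords[1] ** 2)
        data += ring_amplitude * np.sin(2.0 * np.pi * radius / ring_period_vox + phase)
    return Volume3D(data, vol.voxel_size_um, GRAYSCALE)


def save_fiber_phantom(spec: FiberPhantomSpec, outdir, basename: str = "phantom") -> dict:
    """Write a fiber phantom, its ground truth, depth map and a JSON sidecar.

    Returns the mapping of artifact names to file paths.
    """
    os.makedirs(outdir, exist_ok=True)
    vol, truth, depth = generate_fiber_phantom(spec)
    paths = {
        "volume": os.path.join(outdir, f"{basename}.nrrd"),
        "truth": os.path.join(outdir, f"{basename}_truth.nrrd"),
        "depth": os.path.join(outdir, f"{basename}_depth.nrrd"),
        "sidecar": os.path.join(outdir, f"{basename}.json"),
    }
    write_volume(Volume3D(vol.data.astype(np.float32), vol.voxel_size_um), paths["volume"])
    from . import _nrrd

    _nrrd.write_nrrd(
        paths["truth"],
        np.moveaxis(truth.vectors.astype(np.float32), -1, 0),
        spacings=(1.0,) + spec.voxel_size_um,
    )
    _nrrd.write_nrrd(paths["depth"], depth.astype(np.float32), spacings=spec.voxel_size_um)
    sidecar = {"spec": dataclasses.asdict(spec), "files": paths}
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths


def load_phantom_spec(sidecar_path) -> FiberPhantomSpec:
    """Re-ingest a sidecar JSON into the spec that produced it."""
    with open(sidecar_path) as fh:
        payload = json.load(fh)
    spec = dict(payload["spec"])
    for key in ("dims", "voxel_size_um"):
        spec[key] = tuple(spec[key])
    if spec.get("disorganised_range") is not None:
        spec["disorganised_range"] = tuple(spec["disorganised_range"])
    return FiberPhantomSpec(**spec)
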