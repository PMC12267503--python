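"""Per-voxel 3-D structure tensors, their eigensystems and fractional anisotropy.

The structure tensor at a voxel is the neighbourhood-weighted average of
outer products of intensity gradients. The integration neighbourhood is set
by a physical window size so the same parameters apply across scans with
different voxel sizes. The dominant texture direction is the eigenvector of
the *smallest* eigenvalue: intensity varies least along a fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume_io import Volume3D

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

WINDOW_KINDS = ("fwhm", "sigma", "box")

# index pairs of the 6 unique components, in storage order
_COMP = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor stored as its 6 unique components.

    ``components`` has shape (6, depth, row, col) ordered
    (J00, J01, J02, J11, J12, J22). ``boundary_margin_vox`` is the per-axis
    margin (one window width) that downstream statistics should exclude.
    """

    components: np.ndarray
    gradient_scale_um: float
    window_size_um: float
    voxel_size_um: tuple[float, float, float]
    boundary_margin_vox: tuple[int, int, int] = (0, 0, 0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[1:]

    def matrices(self) -> np.ndarray:
        """Assemble dense (..., 3, 3) symmetric matrices (copies)."""
        m = np.empty(self.shape + (3, 3), dtype=self.components.dtype)
        for k, (i, j) in enumerate(_COMP):
            m[..., i, j] = self.components[k]
            m[..., j, i] = self.components[k]
        return m

    def trace(self) -> np.ndarray:
        return self.components[0] + self.components[3] + self.components[5]

    def interior_mask(self) -> np.ndarray:
        """Boolean mask of voxels at least one window width from every face."""
        mask = np.zeros(self.shape, dtype=bool)
        sl = []
        for n, m in zip(self.shape, self.boundary_margin_vox):
            if 2 * m >= n:
                return mask
            sl.append(slice(m, n - m))
        mask[tuple(sl)] = True
        return mask


@dataclass
class EigenField:
    """Per-voxel sorted eigensystem of a TensorField.

    ``eigenvalues`` shape (..., 3), descending. ``eigenvectors`` shape
    (..., 3, 3) with ``eigenvectors[..., :, k]`` the unit eigenvector of
    ``eigenvalues[..., k]``. ``degenerate_mask`` flags voxels whose
    orientation is unreliable (near-zero trace or near-equal lambda2/lambda3).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degenerate_mask: np.ndarray
    boundary_margin_vox: tuple[int, int, int] = (0, 0, 0)

    @property
    def shape(self):
        return self.eigenvalues.shape[:-1]


@dataclass
class OrientationField:
    """Per-voxel axial unit direction (v and -v are equivalent).

    Degenerate voxels carry a null (zero) vector and ``valid`` False.
    """

    vectors: np.ndarray  # (..., 3)
    valid: np.ndarray  # (...,) bool
    boundary_margin_vox: tuple[int, int, int] = (0, 0, 0)

    @property
    def shape(self):
        return self.vectors.shape[:-1]


def _sigma_vox(size_um: float, voxel_size_um, kind: str) -> np.ndarray:
    w_vox = np.asarray(size_um, dtype=float) / np.asarray(voxel_size_um, dtype=float)
    if kind == "fwhm":
        return w_vox / FWHM_TO_SIGMA
    if kind == "sigma":
        return w_vox
    raise ValidationError(f"unknown window kind {kind!r}")


def compute_structure_tensor(
    vol: Volume3D,
    gradient_scale_um: float | None = None,
    window_size_um: float = 123.5,
    window_kind: str = "fwhm",
) -> TensorField:
    """Compute the structure tensor field of a grayscale volume.

    The volume is pre-smoothed with a Gaussian of scale ``gradient_scale_um``
    (default: one voxel per axis), gradients are taken by central differences,
    and the six gradient products are averaged over a window of physical
    extent ``window_size_um`` per axis. ``window_kind`` states how that
    extent is interpreted: Gaussian FWHM (default), Gaussian sigma, or the
    width of a box average. Boundary handling is edge replication; one window
    width from each face is recorded as a margin to exclude from statistics.
    """
    if window_kind not in WINDOW_KINDS:
        raise ValidationError(f"window_kind must be one of {WINDOW_KINDS}, got {window_kind!r}")
    if window_size_um <= 0:
        raise ValidationError("window_size_um must be positive")
    if gradient_scale_um is not None and gradient_scale_um < 0:
        raise ValidationError("gradient_scale_um must be nonnegative")
    vs = np.asarray(vol.voxel_size_um, dtype=float)
    extent = np.asarray(vol.extent_um)
    if (extent <= window_size_um).any():
        raise ValidationError(
            f"volume extent {tuple(extent)} um must exceed window_size_um={window_size_um} on every axis"
        )
    w_vox = window_size_um / vs
    if (w_vox < 1).any():
        raise ValidationError(f"window {window_size_um} um is smaller than one voxel on some axis")

    data = vol.data.astype(np.float64, copy=False)
    if gradient_scale_um is None:
        sigma_g = np.ones(3)  # one voxel per axis
    else:
        sigma_g = gradient_scale_um / vs
    if (sigma_g > 0).any():
        data = ndimage.gaussian_filter(data, sigma=sigma_g, mode="nearest")

    grads = np.gradient(data, *vs, edge_order=1)

    if window_kind == "box":
        size = np.maximum(np.round(w_vox).astype(int), 1)

        def smooth(a):
            return ndimage.uniform_filter(a, size=tuple(size), mode="nearest")
    else:
        sigma_w = _sigma_vox(window_size_um, vs, window_kind)

        def smooth(a):
            return ndimage.gaussian_filter(a, sigma=sigma_w, mode="nearest")

    comps = np.empty((6,) + vol.shape, dtype=np.float64)
    for k, (i, j) in enumerate(_COMP):
        comps[k] = smooth(grads[i] * grads[j])

    margin = tuple(int(np.ceil(w)) for w in w_vox)
    return TensorField(
        components=comps,
        gradient_scale_um=float(gradient_scale_um) if gradient_scale_um is not None else float(np.min(vs)),
        window_size_um=float(window_size_um),
        voxel_size_um=tuple(vs),
        boundary_margin_vox=margin,
    )


def _eig_analytic(comps: np.ndarray):
    """Vectorized eigensystem of symmetric 3x3 fields (trigonometric method).

    ``comps`` shape (6, ...). Returns (eigenvalues descending (..., 3),
    eigenvectors (..., 3, 3) column-matched, isotropic mask).
    """
    a00, a01, a02, a11, a12, a22 = (comps[k] for k in range(6))
    q = (a00 + a11 + a22) / 3.0
    p2 = ((a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2) / 6.0 + (a01**2 + a02**2 + a12**2) / 3.0
    p = np.sqrt(p2)
    scale = np.abs(a00) + np.abs(a11) + np.abs(a22) + np.abs(q)
    isotropic = p <= 1e-14 * (scale + 1e-300)
    p_safe = np.where(isotropic, 1.0, p)

    b00, b11, b22 = (a00 - q) / p_safe, (a11 - q) / p_safe, (a22 - q) / p_safe
    b01, b02, b12 = a01 / p_safe, a02 / p_safe, a12 / p_safe
    detb = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    l1 = q + 2.0 * p * np.cos(phi)
    l3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    l2 = 3.0 * q - l1 - l3
    evals = np.stack([l1, l2, l3], axis=-1)
    evals = np.where(isotropic[..., None], np.stack([q, q, q], axis=-1), evals)

    # Eigenvectors for l1 and l3 from the largest cross product of rows of
    # (A - lambda I); the middle one completes the orthonormal triad.
    def null_vector(lam):
        r0 = np.stack([a00 - lam, a01, a02], axis=-1)
        r1 = np.stack([a01, a11 - lam, a12], axis=-1)
        r2 = np.stack([a02, a12, a22 - lam], axis=-1)
        c01 = np.cross(r0, r1)
        c02 = np.cross(r0, r2)
        c12 = np.cross(r1, r2)
        norms = np.stack(
            [np.linalg.norm(c01, axis=-1), np.linalg.norm(c02, axis=-1), np.linalg.norm(c12, axis=-1)],
            axis=-1,
        )
        pick = np.argmax(norms, axis=-1)
        cand = np.stack([c01, c02, c12], axis=-2)
        v = np.take_along_axis(cand, pick[..., None, None], axis=-2)[..., 0, :]
        n = np.linalg.norm(v, axis=-1, keepdims=True)
        bad = n[..., 0] <= 1e-290
        v = np.where(bad[..., None], np.array([1.0, 0.0, 0.0]), v / np.where(n <= 1e-290, 1.0, n))
        return v, bad

    v1, bad1 = null_vector(l1)
    v3, bad3 = null_vector(l3)
    # Re-orthogonalize v3 against v1 (guards near-degenerate voxels), then
    # complete the triad.
    v3 = v3 - (np.sum(v3 * v1, axis=-1, keepdims=True)) * v1
    n3 = np.linalg.norm(v3, axis=-1, keepdims=True)
    fallback3 = n3[..., 0] <= 1e-8
    # any perpendicular works when v3 degenerated onto v1
    alt = np.cross(v1, np.array([1.0, 0.0, 0.0]))
    alt_n = np.linalg.norm(alt, axis=-1, keepdims=True)
    alt2 = np.cross(v1, np.array([0.0, 1.0, 0.0]))
    alt = np.where(alt_n <= 1e-8, alt2, alt)
    alt = alt / np.linalg.norm(alt, axis=-1, keepdims=True)
    v3 = np.where(fallback3[..., None], alt, v3 / np.where(n3 <= 1e-8, 1.0, n3))
    v2 = np.cross(v3, v1)

    evecs = np.stack([v1, v2, v3], axis=-1)
    ident = np.broadcast_to(np.eye(3), evecs.shape)
    unreliable = isotropic | bad1 | bad3 | fallback3
    evecs = np.where(unreliable[..., None, None], ident, evecs)
    return evals, evecs, isotropic


def eigendecompose_field(tf: TensorField, eps: float = 1e-6) -> EigenField:
    """Eigendecompose every voxel's tensor, sorted descending.

    The analytic 3x3 solver is used voxel-wise; voxels whose residual
    ``|A v - lambda v|`` exceeds tolerance are re-solved with a dense
    symmetric solver. Degenerate voxels — near-zero trace relative to the
    field maximum, or lambda2 ~ lambda3 — are flagged, not dropped.
    """
    comps = tf.components
    if not np.isfinite(comps).all():
        raise ValidationError("tensor field contains non-finite values")
    evals, evecs, _ = _eig_analytic(comps)

    # residual-based refinement with a dense solver
    mats = tf.matrices()
    resid = np.linalg.norm(np.einsum("...ij,...jk->...ik", mats, evecs) - evals[..., None, :] * evecs, axis=-2)
    tr = tf.trace()
    tol = 1e-10 * (np.abs(tr) + np.max(np.abs(tr)) + 1e-300)
    redo = (resid > tol[..., None]).any(axis=-1)
    if redo.any():
        w, v = np.linalg.eigh(mats[redo])  # ascending
        evals[redo] = w[:, ::-1]
        evecs[redo] = v[:, :, ::-1]

    # clip tiny negative eigenvalues (PSD up to rounding)
    neg_tol = 1e-10 * (np.abs(tr) + np.max(np.abs(tr), initial=0.0))
    if (evals[..., 2] < -neg_tol).any():
        raise ValidationError("tensor field is not positive semi-definite within tolerance")
    np.maximum(evals, 0.0, out=evals)

    max_tr = float(np.max(tr, initial=0.0))
    degenerate = (tr <= eps * max_tr) | ((evals[..., 1] - evals[..., 2]) <= eps * evals[..., 0])
    return EigenField(
        eigenvalues=evals,
        eigenvectors=evecs,
        degenerate_mask=degenerate,
        boundary_margin_vox=tf.boundary_margin_vox,
    )


def fractional_anisotropy(eig: EigenField) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, in [0, 1].

    Zero by convention where all eigenvalues vanish.
    """
    lam = eig.eigenvalues
    scale = np.max(np.abs(lam), initial=0.0)
    if (lam < -1e-10 * (scale + 1e-300)).any():
        raise ValidationError("negative eigenvalues beyond tolerance")
    lam = np.maximum(lam, 0.0)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.clip(fa, 0.0, 1.0)


def fiber_directions(eig: EigenField) -> OrientationField:
    """Per-voxel fiber direction: the eigenvector of the smallest eigenvalue.

    Axial semantics (v and -v equivalent); degenerate voxels carry a null
    vector and are marked invalid.
    """
    v = eig.eigenvectors[..., :, 2].copy()
    valid = ~eig.degenerate_mask
    v[~valid] = 0.0
    return OrientationField(vectors=v, valid=valid, boundary_margin_vox=eig.boundary_margin_vox)
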