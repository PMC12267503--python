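import numpy as np
import pytest

from myomap3d.errors import ValidationError
from myomap3d.myomapping import (
    axial_mean_deg,
    compute_myomap,
    default_tissue_mask,
    fit_wall_frame,
    helical_angle,
    intrusion_angle,
    mean_fa,
    sign_normalize,
    transmural_profile,
)
from myomap3d.structure_tensor import OrientationField
from myomap3d.synthetic_data import FiberPhantomSpec, generate_fiber_phantom
from myomap3d.volume_io import BINARY_MASK, ROIBox, Volume3D


def orientation_from_angles(frame, ha_deg, ia_deg=0.0):
    """Build an orientation field with stated HA/IA in the given frame."""
    ha = np.radians(np.broadcast_to(ha_deg, frame.shape))
    ia = np.radians(np.broadcast_to(ia_deg, frame.shape))
    v = (
        np.cos(ia)[..., None] * (np.cos(ha)[..., None] * frame.c + np.sin(ha)[..., None] * frame.l)
        + np.sin(ia)[..., None] * frame.r
    )
    return OrientationField(vectors=v, valid=np.ones(frame.shape, dtype=bool))


class TestWallFrame:
    def test_slab_constant_triad_and_linear_depth(self, full_mask):
        frame = fit_wall_frame(full_mask((8, 6, 6)))
        np.testing.assert_allclose(frame.r[0, 0, 0], [1, 0, 0])
        np.testing.assert_allclose(frame.l[0, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(frame.c[0, 0, 0], np.cross([0, 1, 0], [1, 0, 0]))
        expect = np.arange(8) / 7.0
        np.testing.assert_allclose(frame.depth[:, 3, 3], expect, atol=1e-12)

    def test_triad_orthonormal_right_handed(self, full_mask):
        frame = fit_wall_frame(full_mask((4, 5, 6)), radial_axis=2, longitudinal_axis=0)
        for a, b in (("c", "l"), ("c", "r"), ("l", "r")):
            dots = np.sum(getattr(frame, a) * getattr(frame, b), axis=-1)
            np.testing.assert_allclose(dots, 0.0, atol=1e-8)
        np.testing.assert_allclose(np.cross(frame.c, frame.l), frame.r, atol=1e-8)

    def test_depth_tracks_warped_slab(self):
        # tissue occupies rows [k, k+10) with a shifting offset per column
        mask = np.zeros((20, 8, 8), dtype=np.uint8)
        for y in range(8):
            mask[y : y + 10, y, :] = 1
        frame = fit_wall_frame(Volume3D(mask, (1, 1, 1), BINARY_MASK))
        for y in range(8):
            col = frame.depth[y : y + 10, y, 0]
            np.testing.assert_allclose(col, np.arange(10) / 9.0, atol=1e-12)
        assert np.isnan(frame.depth[0, 5, 0])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            fit_wall_frame(Volume3D(np.zeros((4, 4, 4), np.uint8), (1, 1, 1), BINARY_MASK))

    def test_surface_mode_requires_faces(self, full_mask):
        with pytest.raises(ValidationError):
            fit_wall_frame(full_mask((6, 6, 6)), mode="surface_normal")

    def test_surface_normal_on_spherical_shell(self):
        # analytic oracle: shell normals are radial from the sphere center
        n = 40
        zz, yy, xx = np.mgrid[:n, :n, :n].astype(float)
        center = (n - 1) / 2.0
        r = np.sqrt((zz - center) ** 2 + (yy - center) ** 2 + (xx - center) ** 2)
        tissue = (r >= 8) & (r <= 16)
        epi = r > 16  # outside the outer surface
        endo = r < 8
        frame = fit_wall_frame(
            Volume3D(tissue.astype(np.uint8), (1, 1, 1), BINARY_MASK),
            mode="surface_normal",
            epi_mask=epi,
            endo_mask=endo,
        )
        mid = tissue & (r >= 10) & (r <= 14)
        radial = np.stack([(zz - center), (yy - center), (xx - center)], axis=-1)
        radial /= np.linalg.norm(radial, axis=-1, keepdims=True)
        cos = np.abs(np.sum(frame.r[mid] * radial[mid], axis=-1))
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert np.median(ang) < 3.0
        assert (frame.depth[mid] > 0.05).all() and (frame.depth[mid] < 0.95).all()


class TestAngles:
    def test_ha_cardinal_directions(self, slab_frame):
        frame = slab_frame((4, 4, 4))
        ha, ok = helical_angle(OrientationField(np.broadcast_to(frame.c, (4, 4, 4, 3)), np.ones((4, 4, 4), bool)), frame)
        np.testing.assert_allclose(ha, 0.0, atol=1e-10)
        ha, _ = helical_angle(OrientationField(np.broadcast_to(frame.l, (4, 4, 4, 3)), np.ones((4, 4, 4), bool)), frame)
        np.testing.assert_allclose(ha, 90.0, atol=1e-10)

    def test_ha_45_and_axial_symmetry(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        v = (frame.c + frame.l) / np.sqrt(2)
        f = OrientationField(np.ascontiguousarray(v), np.ones((3, 3, 3), bool))
        ha, _ = helical_angle(f, frame)
        np.testing.assert_allclose(ha, 45.0, atol=1e-10)
        ha_neg, _ = helical_angle(OrientationField(-np.ascontiguousarray(v), f.valid), frame)
        np.testing.assert_allclose(ha_neg, ha, atol=1e-10)

    def test_ha_radial_fiber_invalid(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        f = OrientationField(np.broadcast_to(frame.r, (3, 3, 3, 3)), np.ones((3, 3, 3), bool))
        ha, ok = helical_angle(f, frame)
        assert not ok.any()
        assert np.isnan(ha).all()

    def test_ia_in_plane_zero(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        f = orientation_from_angles(frame, ha_deg=33.0, ia_deg=0.0)
        ia, ok = intrusion_angle(f, frame)
        np.testing.assert_allclose(ia, 0.0, atol=1e-10)
        assert ok.all()

    def test_ia_radial_is_90(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        f = OrientationField(np.broadcast_to(frame.r, (3, 3, 3, 3)), np.ones((3, 3, 3), bool))
        ia, _ = intrusion_angle(f, frame)
        np.testing.assert_allclose(ia, 90.0, atol=1e-10)

    def test_ia_45(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        v = (frame.c + frame.r) / np.sqrt(2)
        ia, _ = intrusion_angle(OrientationField(np.ascontiguousarray(v), np.ones((3, 3, 3), bool)), frame)
        np.testing.assert_allclose(ia, 45.0, atol=1e-10)

    def test_ia_to_radial_convention(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        f = orientation_from_angles(frame, ha_deg=0.0, ia_deg=30.0)
        ia, _ = intrusion_angle(f, frame, convention="to_radial")
        np.testing.assert_allclose(ia, 60.0, atol=1e-8)

    def test_lattice_mismatch(self, slab_frame):
        frame = slab_frame((3, 3, 3))
        f = OrientationField(np.zeros((4, 4, 4, 3)), np.ones((4, 4, 4), bool))
        with pytest.raises(ValidationError):
            helical_angle(f, frame)
        with pytest.raises(ValidationError):
            intrusion_angle(f, frame)

    def test_sign_flip_invariance_random(self, slab_frame, rng):
        frame = slab_frame((6, 6, 6))
        f = orientation_from_angles(frame, ha_deg=rng.uniform(-89, 90, (6, 6, 6)), ia_deg=rng.uniform(-45, 45, (6, 6, 6)))
        flips = rng.random((6, 6, 6)) < 0.5
        flipped = OrientationField(np.where(flips[..., None], -f.vectors, f.vectors), f.valid)
        for fn in (helical_angle, intrusion_angle):
            a0, _ = fn(f, frame)
            a1, _ = fn(flipped, frame)
            np.testing.assert_allclose(a0, a1, atol=1e-9)


class TestTransmuralProfile:
    def test_constant_field(self, slab_frame):
        frame = slab_frame((20, 4, 4))
        angles = np.full((20, 4, 4), 30.0)
        prof = transmural_profile(angles, frame, 5)
        np.testing.assert_allclose(prof.mean_angle, 30.0, atol=1e-9)
        np.testing.assert_allclose(prof.dispersion, 0.0, atol=1e-6)
        assert prof.n.sum() == 20 * 16

    def test_counts_partition_valid_set(self, slab_frame, rng):
        frame = slab_frame((16, 5, 5))
        angles = rng.uniform(-90, 90, (16, 5, 5))
        valid = rng.random((16, 5, 5)) < 0.7
        angles[~valid] = np.nan
        prof = transmural_profile(angles, frame, 7, valid=valid)
        assert prof.n.sum() == valid.sum()

    def test_empty_bins_marked(self, slab_frame):
        frame = slab_frame((20, 3, 3))
        angles = np.full((20, 3, 3), np.nan)
        angles[:5] = 10.0  # only shallow depths populated
        prof = transmural_profile(angles, frame, 10)
        assert prof.empty.any()
        assert np.isnan(prof.mean_angle[prof.empty]).all()

    def test_single_bin_equals_axial_mean(self, slab_frame, rng):
        frame = slab_frame((10, 4, 4))
        angles = rng.uniform(-90, 90, (10, 4, 4))
        prof = transmural_profile(angles, frame, 1)
        mean, disp = axial_mean_deg(angles.ravel())
        assert prof.mean_angle[0] == pytest.approx(mean, abs=1e-9)
        assert prof.dispersion[0] == pytest.approx(disp, abs=1e-9)

    def test_axial_wraparound_mean(self, slab_frame):
        # angles at +89 and -89 average to 90 (axially), not 0
        frame = slab_frame((2, 2, 2))
        angles = np.array([89.0, -89.0, 89.0, -89.0, 89.0, -89.0, 89.0, -89.0]).reshape(2, 2, 2)
        prof = transmural_profile(angles, frame, 1)
        assert abs(abs(prof.mean_angle[0]) - 90.0) < 1e-6

    def test_no_valid_voxels(self, slab_frame):
        frame = slab_frame((4, 4, 4))
        with pytest.raises(ValidationError):
            transmural_profile(np.full((4, 4, 4), np.nan), frame, 4)

    def test_ramp_phantom_tracks_generator(self, full_mask):
        # generator ground truth as oracle for the full pipeline profile
        spec = FiberPhantomSpec(dims=(96, 48, 48), voxel_size_um=(5.8, 5.8, 5.8), seed=9)
        vol, _, _ = generate_fiber_phantom(spec)
        mask = full_mask(vol.shape, vol.voxel_size_um)
        myo = compute_myomap(vol, tissue_mask=mask, window_size_um=60.0)
        frame = fit_wall_frame(mask)
        n_bins = 20
        prof = transmural_profile(myo.HA, frame, n_bins, valid=myo.valid)
        margin = 11 / 95.0  # one window width in depth units
        for b in range(n_bins):
            lo, hi = b / n_bins, (b + 1) / n_bins
            if prof.empty[b] or lo < margin or hi > 1 - margin:
                continue
            expect = 60.0 - 120.0 * prof.bin_centers[b]
            assert abs(prof.mean_angle[b] - expect) < 5.0


class TestMeanFA:
    def test_constant(self):
        fa = np.full((6, 6, 6), 0.5)
        m, n = mean_fa(fa, ROIBox((0, 0, 0), (6, 6, 6)))
        assert m == pytest.approx(0.5)
        assert n == 216

    def test_two_halves(self):
        fa = np.empty((4, 4, 4))
        fa[:2] = 0.2
        fa[2:] = 0.6
        m, n = mean_fa(fa, ROIBox((0, 0, 0), (4, 4, 4)))
        assert m == pytest.approx(0.4)

    def test_mask_region_and_valid(self, rng):
        fa = rng.random((5, 5, 5))
        region = rng.random((5, 5, 5)) < 0.5
        valid = rng.random((5, 5, 5)) < 0.8
        m, n = mean_fa(fa, region, valid=valid)
        sel = region & valid
        assert n == sel.sum()
        assert m == pytest.approx(fa[sel].mean())

    def test_empty_overlap(self):
        fa = np.full((4, 4, 4), np.nan)
        with pytest.raises(ValidationError):
            mean_fa(fa, ROIBox((0, 0, 0), (2, 2, 2)))

    def test_coherent_beats_isotropic_noise(self, full_mask, rng):
        from myomap3d.synthetic_data import add_artefacts

        spec = FiberPhantomSpec(dims=(48, 48, 48), voxel_size_um=(1, 1, 1), ha_epi_deg=10, ha_endo_deg=10, seed=2)
        coherent, _, _ = generate_fiber_phantom(spec)
        noise = add_artefacts(Volume3D(np.zeros((48, 48, 48)), (1, 1, 1)), noise_sigma=1.0, seed=4)
        roi = ROIBox((12, 12, 12), (36, 36, 36))
        means = []
        for vol in (coherent, noise):
            myo = compute_myomap(vol, tissue_mask=full_mask(vol.shape), window_size_um=10.0)
            m, _ = mean_fa(myo.FA, roi, valid=myo.valid)
            means.append(m)
        assert means[0] > means[1]


class TestComputeMyomap:
    def test_default_tissue_mask_runs(self):
        spec = FiberPhantomSpec(dims=(40, 40, 40), voxel_size_um=(1, 1, 1), ha_epi_deg=0, ha_endo_deg=0, seed=6)
        vol, _, _ = generate_fiber_phantom(spec)
        mask = default_tissue_mask(vol)
        assert mask.data.any()
        myo = compute_myomap(vol, window_size_um=8.0)
        assert myo.valid.any()
        assert np.isnan(myo.HA[~myo.valid]).all()

    def test_invalid_voxels_are_nan_everywhere(self, full_mask):
        spec = FiberPhantomSpec(dims=(32, 32, 32), voxel_size_um=(1, 1, 1), seed=8)
        vol, _, _ = generate_fiber_phantom(spec)
        myo = compute_myomap(vol, tissue_mask=full_mask(vol.shape), window_size_um=6.0)
        for fieldname in ("HA", "IA", "FA"):
            arr = getattr(myo, fieldname)
            assert np.isnan(arr[~myo.valid]).all()
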