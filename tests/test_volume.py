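"""Tests for the confocal-stack pipeline and ellipsoid-shell densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromet import (
    BinaryVolume3D,
    CalibratedImage2D,
    decompose_3d,
    fit_core_ellipsoid,
    maxpool_resize,
    measure_3d,
    preprocess_stack,
    remove_spurious_3d,
    shell_profile_3d,
)
from spheromet.phantom import PhantomSpec2D, PhantomSpec3D, make_phantom_2d, make_phantom_3d
from spheromet.segmentation import otsu_threshold

from _oracles import brute_force_3d_zspan_filter, brute_force_otsu


def _ball_volume(shape=(40, 64, 64), centre=None, r_vox=15, xy=2.0, z=2.0):
    zz, yy, xx = np.indices(shape)
    if centre is None:
        centre = [(s - 1) / 2 for s in shape]
    d = np.sqrt(
        ((zz - centre[0]) * z / xy) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    )
    return BinaryVolume3D(d <= r_vox, xy_pixel_size=xy, z_spacing=z)


class TestPreprocessStack:
    def _bimodal_slice(self, rng, shape=(32, 32)):
        img = rng.normal(30, 4, shape)
        img[8:24, 8:24] = rng.normal(200, 4, (16, 16))
        return CalibratedImage2D(img, 1.0)

    def test_median_filter_removes_impulse_noise(self):
        img = np.full((32, 32), 20.0)
        img[5, 5] = 250.0  # single salt pixel
        slices = [CalibratedImage2D(img, 1.0)] * 3
        # the impulse is erased by the median, leaving constant slices ->
        # all-background masks rather than a one-pixel object
        vol = preprocess_stack(slices, z_spacing=3.0)
        assert not vol.voxels.any()

    def test_identical_slices_give_identical_masks(self, rng):
        sl = self._bimodal_slice(rng)
        vol = preprocess_stack([sl, sl, sl, sl], z_spacing=3.0)
        for k in range(1, 4):
            assert np.array_equal(vol.voxels[0], vol.voxels[k])
        assert vol.voxels[0, 12, 12] and not vol.voxels[0, 2, 2]

    def test_per_slice_otsu_matches_exhaustive_search(self, rng):
        imgs = [rng.integers(0, 256, size=(24, 24)).astype(np.uint8) for _ in range(3)]
        from scipy import ndimage

        for img in imgs:
            filt = ndimage.median_filter(img.astype(float), size=3)
            assert otsu_threshold(filt.astype(int)) == brute_force_otsu(filt.astype(int))

    def test_nonuniform_shapes_rejected(self, rng):
        slices = [
            CalibratedImage2D(rng.normal(50, 30, (32, 32)), 1.0),
            CalibratedImage2D(rng.normal(50, 30, (32, 48)), 1.0),
            CalibratedImage2D(rng.normal(50, 30, (32, 32)), 1.0),
        ]
        with pytest.raises(ValueError, match="shape"):
            preprocess_stack(slices, z_spacing=3.0)


class TestRemoveSpurious3D:
    def _vol(self, vox):
        return BinaryVolume3D(vox, xy_pixel_size=1.0, z_spacing=3.0)

    def test_two_slice_object_deleted_three_slice_kept(self):
        vox = np.zeros((16, 16, 16), dtype=bool)
        vox[10:12, 2:4, 2:4] = True   # spans slices {10, 11}
        vox[3:6, 10:12, 10:12] = True  # spans slices {3, 4, 5}
        out = remove_spurious_3d(self._vol(vox), min_slices=3)
        assert not out.voxels[10:12].any()
        assert out.voxels[3:6, 10:12, 10:12].all()

    def test_min_slices_one_is_identity(self, rng):
        vox = rng.random((8, 16, 16)) < 0.1
        out = remove_spurious_3d(self._vol(vox), min_slices=1)
        assert np.array_equal(out.voxels, vox)

    def test_matches_brute_force_labelling(self, rng):
        vox = rng.random((8, 12, 12)) < 0.08
        out = remove_spurious_3d(self._vol(vox), min_slices=3)
        assert np.array_equal(out.voxels, brute_force_3d_zspan_filter(vox, 3))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 4))
    def test_idempotent_and_monotone(self, seed, k):
        rng = np.random.default_rng(seed)
        vol = self._vol(rng.random((8, 12, 12)) < 0.12)
        once = remove_spurious_3d(vol, k)
        assert np.array_equal(remove_spurious_3d(once, k).voxels, once.voxels)
        stricter = remove_spurious_3d(vol, k + 1)
        assert not (stricter.voxels & ~once.voxels).any()


class TestMaxpoolResize:
    def test_halves_dimensions_and_doubles_calibration(self):
        vol = BinaryVolume3D(
            np.zeros((100, 64, 64), dtype=bool), xy_pixel_size=0.24, z_spacing=3.0
        )
        out = maxpool_resize(vol)
        assert out.shape == (50, 32, 32)
        assert out.xy_pixel_size == pytest.approx(0.48)
        assert out.z_spacing == pytest.approx(6.0)

    def test_odd_trailing_planes_truncated(self):
        vol = BinaryVolume3D(np.ones((7, 9, 5), dtype=bool), 1.0, 1.0)
        assert maxpool_resize(vol).shape == (3, 4, 2)

    def test_empty_stays_empty_single_voxel_survives(self):
        empty = BinaryVolume3D(np.zeros((8, 8, 8), bool), 1.0, 1.0)
        assert not maxpool_resize(empty).voxels.any()
        one = np.zeros((8, 8, 8), dtype=bool)
        one[5, 2, 7] = True
        out = maxpool_resize(BinaryVolume3D(one, 1.0, 1.0))
        assert out.voxels.sum() == 1 and out.voxels[2, 1, 3]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_occupancy_bounds(self, seed):
        rng = np.random.default_rng(seed)
        vox = rng.random((8, 10, 12)) < 0.2
        n = vox.sum()
        pooled = maxpool_resize(BinaryVolume3D(vox, 1.0, 1.0)).voxels.sum()
        assert np.ceil(n / 8) <= pooled <= max(n, 1) or n == 0


class TestFitCoreEllipsoid:
    def test_ball_recovered(self):
        vol = _ball_volume(r_vox=15, xy=2.0, z=2.0)
        core = fit_core_ellipsoid(vol)
        for a in core.semi_axes:
            assert a == pytest.approx(30.0, rel=0.05)  # 15 vox * 2 µm

    def test_axis_aligned_ellipsoid_recovered(self):
        truth = make_phantom_3d(
            PhantomSpec3D(shape=(96, 96, 96), xy_pixel_size=1.0, z_spacing=1.0,
                          core_semi_axes=(40, 30, 20), n_rods=0, n_detached=0)
        )
        core = fit_core_ellipsoid(truth.volume)
        assert sorted(core.semi_axes) == pytest.approx([20, 30, 40], rel=0.05)

    def test_thin_spikes_do_not_change_the_core(self):
        truth = make_phantom_3d(
            PhantomSpec3D(shape=(32, 192, 192), core_semi_axes=(10, 20, 16),
                          n_rods=6, rod_radius=4.0, rod_length=120.0,
                          n_detached=0, seed=3)
        )
        with_spikes = fit_core_ellipsoid(truth.volume)
        bare = fit_core_ellipsoid(truth.core_volume)
        assert np.allclose(
            sorted(with_spikes.semi_axes), sorted(bare.semi_axes), rtol=0.05
        )

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            fit_core_ellipsoid(BinaryVolume3D(np.zeros((8, 16, 16), bool), 1.0, 1.0))


class TestShellProfile:
    def test_ball_density_is_a_step_at_t_equal_one(self):
        vol = _ball_volume(r_vox=14)
        dec = decompose_3d(vol)
        prof = shell_profile_3d(dec, step=0.05)
        t = prof.scale_factors
        occupied = prof.shell_voxels > 0
        assert np.all(prof.density_total[(t + 0.05 <= 0.95) & occupied] >= 0.95)
        assert np.all(prof.density_total[t >= 1.1] <= 0.05)

    def test_empty_shells_have_zero_density(self):
        vol = _ball_volume(r_vox=10)
        prof = shell_profile_3d(decompose_3d(vol), step=0.1)
        assert np.all(prof.density_total[prof.scale_factors >= 2.0] == 0.0)
        for name in ("total", "core", "edging", "detached"):
            d = prof.density(name)
            assert np.all((0 <= d) & (d <= 1))

    def test_rod_density_matches_solid_angle_fraction(self):
        """Radial rods of known cross-section: shell density beyond the core
        approximates the covered solid-angle fraction."""
        shape = (96, 96, 96)
        zz, yy, xx = np.indices(shape)
        c = 47.5
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        ball = r <= 20
        rods = np.zeros(shape, dtype=bool)
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        rho = 4.0
        p = np.stack([zz - c, yy - c, xx - c], axis=-1)
        for d in dirs:
            t = p @ d
            perp = np.sqrt(np.maximum((p**2).sum(-1) - t**2, 0))
            rods |= (t >= 18) & (t <= 45) & (perp <= rho)
        vol = BinaryVolume3D(ball | rods, 1.0, 1.0)
        dec = decompose_3d(vol)
        prof = shell_profile_3d(dec, step=0.05)
        # at radius R beyond the core, each rod covers ~ pi*rho^2 / (4 pi R^2)
        t = prof.scale_factors
        mid = (t >= 1.4) & (t <= 1.8)
        R = t[mid] * np.prod(sorted(dec.core_ellipsoid.semi_axes)) ** (1 / 3)
        expected = 6 * np.pi * rho**2 / (4 * np.pi * R**2)
        assert np.all(np.abs(prof.density_total[mid] - expected) <= 0.05)

    def test_component_additivity_within_shell_tolerance(self):
        truth = make_phantom_3d(PhantomSpec3D(seed=5))
        dec = decompose_3d(truth.volume)
        prof = shell_profile_3d(dec, step=0.05)
        parts = prof.density_core + prof.density_edging + prof.density_detached
        tol = 2.0 / np.maximum(prof.shell_voxels, 1)
        assert np.all(np.abs(prof.density_total - parts) <= tol)


class TestMeasure3D:
    def test_ball_volume_matches_closed_form(self):
        # 77 µm radius ball: V = 4/3 pi r^3 = 0.0019 mm^3
        vol = _ball_volume(shape=(80, 80, 80), r_vox=38.5, xy=2.0, z=2.0)
        dec = decompose_3d(vol)
        meas = measure_3d(dec)
        assert meas["total_cell_volume"] == pytest.approx(
            4 / 3 * np.pi * 0.077**3, rel=0.05
        )
        assert meas["total_cell_volume"] == pytest.approx(0.0019, rel=0.05)

    def test_empty_components_have_zero_volume(self):
        vol = _ball_volume(r_vox=12)
        meas = measure_3d(decompose_3d(vol))
        assert meas["detached_volume"] == 0.0

    def test_phantom_volumes_recovered_within_5_percent(self):
        truth = make_phantom_3d(PhantomSpec3D(seed=7))
        dec = decompose_3d(truth.volume)
        meas = measure_3d(dec)
        assert meas["total_cell_volume"] == pytest.approx(
            truth.volume.volume_mm3(), rel=0.05
        )
        assert meas["core_volume"] == pytest.approx(
            truth.core_volume.volume_mm3(), rel=0.05
        )
        assert meas["detached_volume"] == pytest.approx(
            truth.detached_volume.volume_mm3(), rel=0.05
        )

    def test_additivity_exact(self):
        truth = make_phantom_3d(PhantomSpec3D(seed=8))
        meas = measure_3d(decompose_3d(truth.volume))
        assert meas["total_cell_volume"] == pytest.approx(
            meas["core_volume"] + meas["edging_volume"] + meas["detached_volume"],
            abs=1e-15,
        )


def test_projection_reaches_at_most_the_3d_extent():
    """The z-projection of a 3D phantom, measured in 2D, cannot reach farther
    than the true 3D maximal extent (projection merges, never extends)."""
    from spheromet import (
        BinaryMask2D,
        decompose,
        invasion_distances,
        largest_inscribed_circle,
    )

    truth = make_phantom_3d(PhantomSpec3D(seed=9))
    proj = truth.volume.voxels.any(axis=0)
    mask = BinaryMask2D(proj, truth.volume.xy_pixel_size)
    dec = decompose(mask, largest_inscribed_circle(mask))
    centre = (truth.core_ellipsoid.centre[1], truth.core_ellipsoid.centre[2])
    d1_2d, _ = invasion_distances(dec, centre)
    assert d1_2d <= truth.farthest_cell_distance_um / 1000 + 1e-9
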