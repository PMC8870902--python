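import numpy as np
import pytest

from gelpen.errors import DegenerateFitError, EmptyMaskError
from gelpen.preprocess import ValidityMask
from gelpen.stack_io import VoxelGeometry
from gelpen.surface import (
    DepthMap,
    POLY_EXPONENTS,
    SurfaceModel,
    compute_penetration,
    extract_surface,
    fit_reference_surface,
    histogram_mode,
    normalized_coords,
    polynomial_design,
)

from oracles import lstsq_normal_equations


def all_valid(shape):
    return ValidityMask(np.ones(shape, dtype=bool))


def depth_from(z, dz=2.0, dy=1.0, dx=1.0, valid=None):
    z = np.asarray(z, dtype=np.float64)
    geom = VoxelGeometry(nz=max(int(np.ceil(np.nanmax(z) / dz)) + 1, 2), ny=z.shape[0], nx=z.shape[1],
                         dz=dz, dy=dy, dx=dx)
    v = all_valid(z.shape) if valid is None else valid
    return DepthMap(z_um=np.where(v.mask, z, np.nan), valid=v, geometry=geom)


class TestExtractSurface:
    def make_volume(self, profile, ny=4, nx=5):
        col = np.asarray(profile, dtype=np.float64)
        return np.tile(col[:, None, None], (1, ny, nx))

    def test_step_profile_crosses_at_midpoint(self):
        # dark for z<5 slices, bright from slice 5 at dz=1: crossing at 4.5
        vol = self.make_volume([0] * 5 + [100] * 5)
        geom = VoxelGeometry(10, 4, 5, dz=1.0, dy=1.0, dx=1.0)
        dm = extract_surface(vol, geom, all_valid((4, 5)))
        np.testing.assert_allclose(dm.z_um, 4.5)

    def test_linear_ramp_crosses_at_center(self):
        vol = self.make_volume(np.linspace(0, 100, 11))
        geom = VoxelGeometry(11, 4, 5, dz=1.0, dy=1.0, dx=1.0)
        dm = extract_surface(vol, geom, all_valid((4, 5)))
        np.testing.assert_allclose(dm.z_um, 5.0)

    def test_dz_scales_physical_depth(self):
        vol = self.make_volume([0, 0, 100, 100])
        geom = VoxelGeometry(4, 4, 5, dz=2.5, dy=1.0, dx=1.0)
        dm = extract_surface(vol, geom, all_valid((4, 5)))
        np.testing.assert_allclose(dm.z_um, 1.5 * 2.5)

    def test_affine_intensity_rescaling_invariance(self, rng):
        vol = rng.random((12, 8, 8)).cumsum(axis=0)  # monotone noisy profiles
        geom = VoxelGeometry(12, 8, 8, dz=1.0, dy=1.0, dx=1.0)
        valid = all_valid((8, 8))
        a, b = 3.7, 11.0
        d1 = extract_surface(vol, geom, valid)
        d2 = extract_surface(a * vol + b, geom, valid)
        np.testing.assert_allclose(d1.z_um, d2.z_um, atol=1e-9)

    def test_flat_columns_marked_invalid(self):
        vol = self.make_volume([0, 0, 100, 100])
        vol[:, 0, 0] = 7.0  # constant column
        geom = VoxelGeometry(4, 4, 5, dz=1.0, dy=1.0, dx=1.0)
        dm = extract_surface(vol, geom, all_valid((4, 5)))
        assert not dm.valid.mask[0, 0]
        assert np.isnan(dm.z_um[0, 0])

    def test_noisy_sigmoid_profiles_recover_inflection(self, rng):
        # Monte-Carlo: logistic profiles with known centre z0, noise, presmooth
        nz, n = 40, 1000
        dz = 1.0
        z = np.arange(nz)
        z0 = rng.uniform(8, 30, size=n)
        prof = 100.0 / (1.0 + np.exp(-(z[:, None] - z0[None]) / 1.5))
        prof += rng.normal(0, 4.0, size=prof.shape)
        vol = prof.reshape(nz, 1, n).clip(0)
        geom = VoxelGeometry(nz, 1, n, dz=dz, dy=1.0, dx=1.0)
        dm = extract_surface(vol, geom, all_valid((1, n)), presmooth_sigma_px=1.0)
        assert np.mean(np.abs(dm.z_um[0] - z0)) <= dz


class TestFitReferenceSurface:
    def test_exact_cubic_is_reproduced(self):
        ny = nx = 64
        xn, yn, norm = normalized_coords(ny, nx)
        z = 3 + 2 * xn - yn + 0.5 * xn * yn**2
        dm = depth_from(z + 10.0)  # shift up to keep depths >= 0
        model = fit_reference_surface(dm)
        pred = model.evaluate(ny, nx)
        assert np.max(np.abs(pred - (z + 10.0))) < 1e-8
        assert model.rmse_um < 1e-9

    def test_constant_map_gives_constant_polynomial(self):
        dm = depth_from(np.full((16, 16), 12.5))
        model = fit_reference_surface(dm)
        np.testing.assert_allclose(model.evaluate(16, 16), 12.5, atol=1e-10)

    def test_matches_normal_equations_oracle_with_noise(self, rng):
        ny = nx = 128
        xn, yn, _ = normalized_coords(ny, nx)
        z = 30 + 5 * xn - 3 * yn**3 + rng.normal(0, 2.0, size=(ny, nx))
        mask = np.ones((ny, nx), bool)
        mask[:5] = False  # some invalid pixels to exercise masking
        dm = depth_from(z, dz=1.0, valid=ValidityMask(mask))
        model = fit_reference_surface(dm)
        A = polynomial_design(xn[mask], yn[mask])
        ref = lstsq_normal_equations(A, z[mask])
        np.testing.assert_allclose(model.coeffs, ref, rtol=1e-6)

    def test_too_few_valid_pixels_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[0, :5] = True
        with pytest.raises(DegenerateFitError):
            fit_reference_surface(depth_from(np.ones((8, 8)), valid=ValidityMask(mask)))

    def test_collinear_mask_is_rank_deficient(self):
        mask = np.zeros((16, 16), bool)
        mask[3, :] = True  # a single row cannot constrain y terms
        with pytest.raises(DegenerateFitError):
            fit_reference_surface(depth_from(np.ones((16, 16)), valid=ValidityMask(mask)))

    def test_basis_has_ten_total_degree_terms(self):
        assert len(POLY_EXPONENTS) == 10
        assert all(i + j <= 3 for i, j in POLY_EXPONENTS)


class TestHistogramMode:
    def test_zero_centred_data_has_zero_mode(self, rng):
        vals = rng.normal(0, 0.3, size=2000)
        assert histogram_mode(vals, 1.0) == 0.0

    def test_shifted_data_mode_snaps_to_bin_centre(self, rng):
        vals = 7.2 + rng.normal(0, 0.2, size=2000)
        assert histogram_mode(vals, 1.0) == 7.0

    def test_tie_resolves_toward_zero(self):
        vals = np.array([5.0, 5.0, -2.0, -2.0])
        assert histogram_mode(vals, 1.0) == -2.0


class TestComputePenetration:
    def test_depth_equal_to_model_gives_zero_map(self):
        dm = depth_from(np.full((32, 32), 20.0))
        model = fit_reference_surface(dm)
        pen = compute_penetration(dm, model, sigma_um=0.0)
        np.testing.assert_allclose(pen.value_um, 0.0, atol=1e-9)
        assert pen.mode_shift_um == 0.0

    def test_single_deep_pixel_on_flat_reference(self):
        z = np.full((100, 100), 30.0)
        z[40, 60] += 10.0  # one pixel 10 µm deeper
        dm = depth_from(z)
        model = SurfaceModel(coeffs=[30.0] + [0.0] * 9,
                             norm=normalized_coords(100, 100)[2], rmse_um=0.0)
        pen = compute_penetration(dm, model, sigma_um=0.0, bin_um=1.0)
        assert pen.value_um[40, 60] == pytest.approx(-10.0, abs=1e-9)
        assert pen.mode_shift_um == 0.0
        others = np.ones((100, 100), bool)
        others[40, 60] = False
        np.testing.assert_allclose(pen.value_um[others], 0.0, atol=1e-9)

    def test_mode_recentering_invariant(self, rng):
        # noisy flat surface: recomputed mode of the output is within a bin of 0
        z = 25.0 + rng.normal(0, 1.5, size=(64, 64))
        dm = depth_from(z)
        model = fit_reference_surface(dm)
        pen = compute_penetration(dm, model, sigma_um=0.0, bin_um=1.0)
        remode = histogram_mode(pen.value_um[pen.valid.mask], pen.bin_um)
        assert abs(remode) <= pen.bin_um

    def test_constant_depth_offset_is_absorbed(self, rng):
        z = 30.0 + rng.normal(0, 1.0, size=(48, 48))
        dm1 = depth_from(z)
        dm2 = depth_from(z + 17.0)
        pen1 = compute_penetration(dm1, fit_reference_surface(dm1), sigma_um=2.0)
        pen2 = compute_penetration(dm2, fit_reference_surface(dm2), sigma_um=2.0)
        np.testing.assert_allclose(pen1.value_um, pen2.value_um, atol=1e-8)

    def test_smoothing_does_not_leak_across_invalid_pixels(self):
        z = np.full((40, 40), 10.0)
        mask = np.ones((40, 40), bool)
        mask[:, 20:] = False
        z[:, 20:] = 1e6  # garbage values behind the mask must not spread
        dm = depth_from(np.where(mask, z, np.nan), valid=ValidityMask(mask))
        model = SurfaceModel(coeffs=[10.0] + [0.0] * 9,
                             norm=normalized_coords(40, 40)[2], rmse_um=0.0)
        pen = compute_penetration(dm, model, sigma_um=3.0)
        np.testing.assert_allclose(pen.value_um[mask], 0.0, atol=1e-9)

    def test_empty_mask_raises(self):
        mask = ValidityMask(np.zeros((8, 8), bool))
        dm = depth_from(np.ones((8, 8)), valid=mask)
        model = SurfaceModel(coeffs=[1.0] + [0.0] * 9,
                             norm=normalized_coords(8, 8)[2], rmse_um=0.0)
        with pytest.raises(EmptyMaskError):
            compute_penetration(dm, model)
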