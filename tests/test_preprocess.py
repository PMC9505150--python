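"""Unit conversions, rasterization, resampling and discretization."""

import numpy as np
import pytest

from dosiomics.imaging import ContourSet, DoseGrid, ImageVolume, RoiMask, Unit
from dosiomics.preprocess import (apply_roi, discretize_fbn, point_in_polygon,
                                  rasterize, resample_mask, resample_trilinear,
                                  round_ct, segment_pet_fixed_threshold,
                                  to_bed, to_suv)

import oracles


def _vol(values, spacing=(1, 1, 1), unit=Unit.HU):
    return ImageVolume(np.asarray(values, dtype=float), spacing, unit=unit)


class TestSuv:
    def test_unit_ratio(self):
        pet = _vol(np.full((2, 2, 2), 1000.0), unit=Unit.BQ_ML)
        suv = to_suv(pet, body_weight_g=70_000, injected_activity_bq=70_000_000,
                     delay_s=0, half_life_s=6000)
        assert np.allclose(suv.values, 1.0)
        assert suv.unit is Unit.SUV

    def test_one_half_life_doubles(self, rng):
        pet = _vol(rng.uniform(10, 100, (3, 3, 3)), unit=Unit.BQ_ML)
        s0 = to_suv(pet, 7e4, 7e8, delay_s=0, half_life_s=1200)
        s1 = to_suv(pet, 7e4, 7e8, delay_s=1200, half_life_s=1200)
        assert np.allclose(s1.values, 2 * s0.values)

    def test_matches_voxelwise_oracle(self, rng):
        vals = rng.uniform(0, 5000, (4, 3, 2))
        pet = _vol(vals, unit=Unit.BQ_ML)
        w, a0, dt, hl = 8.1e4, 3.3e8, 777.0, 1223.4
        suv = to_suv(pet, w, a0, dt, hl)
        for idx in np.ndindex(vals.shape):
            expected = vals[idx] * w / (a0 * 2 ** (-dt / hl))
            assert suv.values[idx] == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_metadata(self):
        pet = _vol(np.ones((2, 2, 2)), unit=Unit.BQ_ML)
        with pytest.raises(ValueError):
            to_suv(pet, -1, 1e8, 0, 1200)


class TestBed:
    def test_prescription_value(self):
        dose = DoseGrid(_vol(np.full((2, 2, 2), 35.0), unit=Unit.GY), n_fractions=7)
        bed = to_bed(dose, alpha_beta_gy=1.5)
        assert round(float(bed.values[0, 0, 0]), 1) == 151.7

    def test_zero_dose(self):
        dose = DoseGrid(_vol(np.zeros((2, 2, 2)), unit=Unit.GY), 7)
        assert np.all(to_bed(dose).values == 0)

    def test_half_prescription_closed_form(self):
        dose = DoseGrid(_vol(np.full((1, 1, 1), 14.0), unit=Unit.GY), 7)
        # 14 * (1 + 2/1.5)
        assert to_bed(dose, 1.5).values[0, 0, 0] == pytest.approx(14 * (1 + 2 / 1.5))

    def test_rejects_nonpositive_alpha_beta(self):
        dose = DoseGrid(_vol(np.ones((1, 1, 1)), unit=Unit.GY), 7)
        with pytest.raises(ValueError):
            to_bed(dose, 0.0)


SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]


class TestPointInPolygon:
    @pytest.mark.parametrize("point,expected", [
        ((0.5, 0.5), True), ((2.0, 0.5), False), ((-0.1, 0.5), False),
    ])
    def test_square(self, point, expected):
        assert point_in_polygon(point, SQUARE) is expected

    def test_concave_polygon_matches_winding_oracle(self, rng):
        # a star-shaped (concave) 10-gon around the origin
        ang = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        rad = np.where(np.arange(10) % 2 == 0, 2.0, 0.7)
        poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        pts = rng.uniform(-2.5, 2.5, size=(200, 2))
        for p in pts:
            assert point_in_polygon(p, poly) == oracles.winding_number_inside(p, poly)

    def test_degenerate_polygon_is_outside(self):
        with pytest.warns(UserWarning):
            assert point_in_polygon((0, 0), [(0, 0), (1, 1), (2, 2)]) is False


class TestRasterize:
    def test_square_block_count(self):
        ref = _vol(np.zeros((3, 10, 10)))
        # square strictly containing the 4x4 block of centres x,y in [2, 5]
        poly = [(1.6, 1.6), (5.4, 1.6), (5.4, 5.4), (1.6, 5.4)]
        contours = ContourSet("GTV", [(1.0, poly)])
        mask = rasterize(contours, ref)
        assert mask.values.sum() == 16
        assert mask.values[1].sum() == 16  # only the z=1 slice

    def test_empty_contourset(self):
        ref = _vol(np.zeros((3, 4, 4)))
        mask = rasterize(ContourSet("GTV", []), ref)
        assert mask.values.sum() == 0

    def test_out_of_grid_plane_raises(self):
        ref = _vol(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="outside"):
            rasterize(ContourSet("GTV", [(9.0, SQUARE)]), ref)

    def test_phantom_gtv_volume_close_to_analytic(self, patient):
        record, _ = patient
        mask = rasterize(record.gtv, record.ct)
        vol = mask.values.sum() * np.prod(record.ct.spacing_mm)
        # compare to sphere of the configured mean radius (8 mm, jitter 1 mm)
        analytic = 4 / 3 * np.pi * 8.0 ** 3
        assert abs(vol - analytic) / analytic < 0.3

    def test_exact_ellipsoid_volume_at_1mm(self):
        from dosiomics.phantom import PhantomParams, generate_patient
        params = PhantomParams(grid_shape=(48, 48, 48), spacing_mm=(1, 1, 1),
                               gtv_radius_mm=(8.0, 0.0), seed=3)
        record, _ = generate_patient(params, np.random.default_rng(3))
        mask = rasterize(record.gtv, record.ct)
        vol = float(mask.values.sum())
        analytic = 4 / 3 * np.pi * 8.0 ** 3
        assert abs(vol - analytic) / analytic < 0.15


class TestResample:
    def test_identity_when_aligned(self, rng):
        vol = _vol(rng.uniform(size=(4, 5, 6)))
        out = resample_trilinear(vol, (1, 1, 1))
        assert out.shape == vol.shape
        assert np.allclose(out.values, vol.values)

    def test_linear_midpoint(self):
        vals = np.zeros((1, 1, 2))
        vals[0, 0, 1] = 10.0
        vol = ImageVolume(vals, (2, 2, 2))
        out = resample_trilinear(vol, (2, 2, 1))
        # input centres at x = 0 and 2 (values 0, 10); output centres at
        # x = -0.5, 0.5, 1.5, 2.5 -> linear interpolation at 0.5 and 1.5
        assert out.values[0, 0, 1] == pytest.approx(2.5)
        assert out.values[0, 0, 2] == pytest.approx(7.5)

    def test_matches_eight_corner_oracle(self, rng):
        vol = _vol(rng.uniform(size=(6, 6, 6)), spacing=(2.0, 2.0, 2.0))
        out = resample_trilinear(vol, (1.0, 1.0, 1.0))
        for _ in range(50):
            idx = tuple(int(rng.integers(2, 9)) for _ in range(3))
            point = [o + s * i for o, s, i in
                     zip(out.origin_mm, out.spacing_mm, idx)]
            expected = oracles.trilinear_at(vol.values, vol.spacing_mm,
                                            vol.origin_mm, point)
            assert out.values[idx] == pytest.approx(expected, rel=1e-10)

    def test_no_overshoot(self, rng):
        vol = _vol(rng.uniform(5, 9, size=(5, 7, 6)), spacing=(1.7, 2.3, 2.9))
        out = resample_trilinear(vol, (1, 1, 1))
        assert out.values.min() >= vol.values.min() - 1e-12
        assert out.values.max() <= vol.values.max() + 1e-12

    def test_mask_binarization(self):
        m = RoiMask(np.pad(np.ones((1, 1, 2)), ((1, 1), (1, 1), (1, 1))),
                    (2.0, 2.0, 2.0))
        out = resample_mask(m, (1.0, 1.0, 1.0), threshold=0.5)
        assert set(np.unique(out.values)) <= {0.0, 1.0}
        assert out.values.sum() > 0

    def test_too_coarse_target_raises(self):
        vol = _vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            resample_trilinear(vol, (100, 1, 1))


class TestRoundCt:
    @pytest.mark.parametrize("value,expected", [(39.6, 40.0), (-0.5, -1.0),
                                                (0.5, 1.0), (2.0, 2.0)])
    def test_rounding_rule(self, value, expected):
        ct = _vol(np.full((1, 1, 1), value))
        assert round_ct(ct).values[0, 0, 0] == expected

    def test_idempotent_on_integers(self, rng):
        ct = _vol(rng.integers(-100, 100, (4, 4, 4)).astype(float))
        assert np.array_equal(round_ct(ct).values, ct.values)


class TestApplyRoi:
    def test_identity_and_degenerate_masks(self, rng):
        vol = _vol(rng.uniform(size=(3, 3, 3)))
        ones = RoiMask(np.ones((3, 3, 3)), (1, 1, 1))
        zeros = RoiMask(np.zeros((3, 3, 3)), (1, 1, 1))
        assert np.array_equal(apply_roi(vol, ones).values, vol.values)
        assert np.all(np.isnan(apply_roi(vol, zeros).values))

    def test_conservation(self, rng):
        vol = _vol(rng.uniform(size=(4, 4, 4)))
        mask = RoiMask((rng.uniform(size=(4, 4, 4)) > 0.5).astype(float), (1, 1, 1))
        out = apply_roi(vol, mask)
        assert np.isfinite(out.values).sum() == mask.values.sum()

    def test_geometry_mismatch(self, rng):
        vol = _vol(rng.uniform(size=(3, 3, 3)))
        mask = RoiMask(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            apply_roi(vol, mask)


class TestDiscretize:
    def test_edges_and_hand_example(self):
        vals = np.full((1, 1, 4), np.nan)
        vals[0, 0, :3] = [0.0, 0.5, 1.0]
        out = discretize_fbn(_vol(vals), n_levels=4)
        assert list(out.values[0, 0, :3]) == [1.0, 3.0, 4.0]
        assert np.isnan(out.values[0, 0, 3])

    def test_constant_roi_maps_to_level_one(self):
        out = discretize_fbn(_vol(np.full((2, 2, 2), 7.0)), 64)
        assert np.all(out.values == 1.0)

    def test_affine_invariance(self, rng):
        vals = rng.uniform(size=(4, 4, 4))
        a = discretize_fbn(_vol(vals), 64)
        b = discretize_fbn(_vol(3.7 * vals - 11.0), 64)
        assert np.array_equal(a.values, b.values)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            discretize_fbn(_vol(np.full((2, 2, 2), np.nan)))


class TestPetSegmentation:
    def test_threshold_arithmetic(self):
        vals = np.ones((3, 5, 5))
        vals[1, 2, 2] = 10.0
        vals[1, 2, 3] = 5.0
        pet = _vol(vals, unit=Unit.SUV)
        region = RoiMask(np.ones((3, 5, 5)), (1, 1, 1))
        seg = segment_pet_fixed_threshold(pet, region, 0.40)
        assert seg.values.sum() == 2  # exactly the voxels >= 4

    def test_fraction_one_keeps_argmax_only(self):
        vals = np.zeros((2, 3, 3))
        vals[0, 1, 1] = 9.0
        pet = _vol(vals, unit=Unit.SUV)
        region = RoiMask(np.ones((2, 3, 3)), (1, 1, 1))
        seg = segment_pet_fixed_threshold(pet, region, 0.999999)
        assert seg.values.sum() == 1
        assert seg.values[0, 1, 1] == 1

    def test_disjoint_blob_removed(self):
        vals = np.zeros((1, 3, 9))
        vals[0, 1, 1] = 8.0   # secondary blob above threshold
        vals[0, 1, 7] = 10.0  # global max
        pet = _vol(vals, unit=Unit.SUV)
        region = RoiMask(np.ones((1, 3, 9)), (1, 1, 1))
        seg = segment_pet_fixed_threshold(pet, region, 0.40)
        assert seg.values[0, 1, 7] == 1 and seg.values[0, 1, 1] == 0
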