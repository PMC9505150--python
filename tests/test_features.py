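"""Shape, intensity, histogram and texture features."""

import numpy as np
import pytest

from dosiomics.features import (FEATURE_NAMES, extract_all, glcm_features,
                                glrlm_features, glszm_features,
                                histogram_features, integrated_intensity,
                                intensity_statistics, ngldm_features,
                                ngtdm_features, shape_features)
from dosiomics.features import matrices, texture
from dosiomics.features.catalogue import build_catalogue
from dosiomics.imaging import ImageVolume, RoiMask, Unit

import oracles
from conftest import random_roi


def _masked(vals, unit=Unit.HU):
    return ImageVolume(np.asarray(vals, dtype=float), (1, 1, 1), unit=unit)


class TestCatalogue:
    def test_closure_and_uniqueness(self):
        cat = build_catalogue()
        names = [d.name for d in cat]
        assert len(names) == 380 == len(set(names))
        assert sum(d.modality == "BED" for d in cat) == 121

    def test_headline_features_present(self):
        # the four predictors reported for the dosiomic signature
        for name in ("BED_stat_variance", "BED_stat_energy",
                     "BED_intensity_integrated_intensity",
                     "BED_glszm_large_zone_high_grey_level_emphasis"):
            assert name in FEATURE_NAMES


class TestShape:
    def test_digital_ball_sphericity(self):
        r = 10
        ax = np.arange(-13, 14)
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = (zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2)
        mask = RoiMask(ball.astype(float), (1, 1, 1))
        f = shape_features(mask)
        assert 0.97 <= f["sphericity"] <= 1.0
        assert f["elongation"] == pytest.approx(1.0, abs=0.02)
        assert abs(f["voxel_volume"] - 4 / 3 * np.pi * r ** 3) / (4 / 3 * np.pi * r ** 3) < 0.05

    def test_single_voxel(self):
        mask = RoiMask(np.pad(np.ones((1, 1, 1)), 1), (1, 1, 1))
        f = shape_features(mask)
        assert f["voxel_volume"] == 1.0

    def test_max_diameter_against_bruteforce(self, rng):
        vals = (rng.uniform(size=(6, 6, 6)) < 0.1)
        while vals.sum() < 2:
            vals = (rng.uniform(size=(6, 6, 6)) < 0.2)
        mask = RoiMask(vals.astype(float), (1, 1, 1))
        f = shape_features(mask)
        centers = np.argwhere(vals).astype(float)
        d = 0.0
        for a in centers:
            for b in centers:
                d = max(d, np.sqrt(((a - b) ** 2).sum()))
        assert f["max_3d_diameter"] == pytest.approx(d, rel=1e-9)

    def test_translation_invariance(self):
        base = np.zeros((8, 8, 8))
        base[2:5, 2:6, 2:4] = 1
        shifted = np.roll(base, (2, 1, 3), axis=(0, 1, 2))
        fa = shape_features(RoiMask(base, (1, 1, 1)))
        fb = shape_features(RoiMask(shifted, (1, 1, 1)))
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], rel=1e-5), k


class TestIntensityStats:
    def test_hand_values(self):
        vals = np.array([1.0, 2, 3, 4]).reshape(1, 1, 4)
        f = intensity_statistics(_masked(vals))
        assert f["variance"] == pytest.approx(1.25)  # population form
        assert f["mean"] == pytest.approx(2.5)
        assert f["energy"] == pytest.approx(30.0)

    def test_energy_two_values(self):
        f = intensity_statistics(_masked(np.array([1.0, 2.0]).reshape(1, 1, 2)))
        assert f["energy"] == pytest.approx(5.0)

    def test_constant_roi_conventions(self):
        f = intensity_statistics(_masked(np.full((2, 2, 2), 3.0)))
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            intensity_statistics(_masked(np.full((2, 2, 2), np.nan)))


class TestIntegratedIntensity:
    def test_definition(self):
        mask = RoiMask(np.ones((1, 1, 10)), (1, 1, 1))
        vol = _masked(np.full((1, 1, 10), 2.0))
        assert integrated_intensity(vol, mask) == pytest.approx(20.0)

    def test_homogeneity(self, rng):
        vals = rng.uniform(1, 5, (2, 3, 4))
        mask = RoiMask(np.ones((2, 3, 4)), (1, 1, 1))
        a = integrated_intensity(_masked(vals), mask)
        b = integrated_intensity(_masked(2 * vals), mask)
        assert b == pytest.approx(2 * a)


class TestHistogram:
    def test_degenerate_and_fair_coin(self):
        single = _masked(np.ones((2, 2, 2)), unit=Unit.GREY_LEVEL)
        f = histogram_features(single, 64)
        assert f["entropy"] == 0.0 and f["uniformity"] == 1.0
        two = np.ones((1, 1, 4))
        two[0, 0, 2:] = 2.0
        f2 = histogram_features(_masked(two, unit=Unit.GREY_LEVEL), 64)
        assert f2["entropy"] == pytest.approx(1.0)

    def test_matches_direct_tally(self, rng):
        x = rng.integers(1, 11, size=100).astype(float)
        vol = _masked(x.reshape(4, 5, 5), unit=Unit.GREY_LEVEL)
        f = histogram_features(vol, n_levels=10)
        counts = np.array([(x == g).sum() for g in range(1, 11)], dtype=float)
        p = counts / counts.sum()
        assert f["mean"] == pytest.approx(x.mean())
        assert f["variance"] == pytest.approx(x.var())
        assert f["mode"] == float(np.argmax(counts) + 1)
        nz = p > 0
        assert f["entropy"] == pytest.approx(-(p[nz] * np.log2(p[nz])).sum())
        assert f["uniformity"] == pytest.approx((p ** 2).sum())
        assert f["p10"] == pytest.approx(np.percentile(x, 10))


class TestTextureMatrices:
    """Element-wise equivalence with the explicit-loop oracle builders."""

    def test_glcm_matrix_matches_loop(self, rng):
        levels = random_roi(rng, (5, 5, 5), 6)
        for d in matrices.DIRECTIONS_13[:5]:
            np.testing.assert_array_equal(matrices.glcm(levels, 6, d),
                                          oracles.glcm_loop(levels, 6, d))

    def test_glrlm_matrix_matches_loop(self, rng):
        levels = random_roi(rng, (5, 5, 5), 4)
        for d in matrices.DIRECTIONS_13:
            np.testing.assert_array_equal(matrices.glrlm(levels, 4, d),
                                          oracles.glrlm_loop(levels, 4, d))

    def test_glszm_matrix_matches_loop(self, rng):
        levels = random_roi(rng, (6, 6, 6), 3)
        np.testing.assert_array_equal(matrices.glszm(levels, 3),
                                      oracles.glszm_loop(levels, 3))

    def test_ngldm_matrix_matches_loop(self, rng):
        levels = random_roi(rng, (5, 5, 5), 4)
        np.testing.assert_array_equal(matrices.ngldm(levels, 4),
                                      oracles.ngldm_loop(levels, 4))

    def test_ngtdm_vectors_match_loop(self, rng):
        levels = random_roi(rng, (5, 5, 5), 5)
        s, n, p = matrices.ngtdm(levels, 5)
        so, no, po = oracles.ngtdm_loop(levels, 5)
        np.testing.assert_allclose(s, so, atol=1e-12)
        np.testing.assert_array_equal(n, no)

    def test_glcm_symmetry(self, rng):
        levels = random_roi(rng, (5, 5, 5), 6)
        for d in matrices.DIRECTIONS_13:
            m = matrices.glcm(levels, 6, d)
            np.testing.assert_array_equal(m, m.T)

    def test_normalized_matrices_sum_to_one(self, rng):
        levels = random_roi(rng, (5, 5, 5), 6, nan_fraction=0.1)
        for d in matrices.DIRECTIONS_13:
            m = matrices.glcm(levels, 6, d)
            if m.sum():
                assert (m / m.sum()).sum() == pytest.approx(1.0, abs=1e-9)
        for m in (matrices.glszm(levels, 6), matrices.ngldm(levels, 6)):
            assert (m / m.sum()).sum() == pytest.approx(1.0, abs=1e-9)


class TestTextureFeatures:
    def test_lzhge_four_singleton_zones(self):
        levels = np.array([[[1.0, 2.0], [3.0, 4.0]]]).reshape(2, 2, 1)
        f = glszm_features(levels, 4)
        # four zones of size 1: LZHGE = sum i^2 * 1 / 4
        assert f["large_zone_high_grey_level_emphasis"] == pytest.approx(
            (1 + 4 + 9 + 16) / 4)
        assert f["small_zone_emphasis"] == 1.0

    def test_constant_roi_conventions(self):
        levels = np.ones((3, 3, 3))
        f = glcm_features(levels, 4)
        assert f["contrast"] == 0.0
        assert f["correlation"] == 1.0
        assert f["joint_maximum"] == 1.0

    def test_all_finite_on_phantom_roi(self, rng):
        levels = random_roi(rng, (6, 6, 6), 8, nan_fraction=0.3)
        for fn in (glcm_features, glrlm_features, glszm_features,
                   ngtdm_features, ngldm_features):
            for k, v in fn(levels, 8).items():
                assert np.isfinite(v), (fn.__name__, k)


class TestExtractAll:
    def test_length_and_determinism(self, preprocessed):
        v1 = extract_all(preprocessed)
        v2 = extract_all(preprocessed)
        assert len(v1) == 380
        assert np.all(np.isfinite(v1.values))
        assert (v1 == v2).all()
        assert list(v1.index) == list(FEATURE_NAMES)

    def test_intensity_translation_invariance(self, rng):
        """Shifting mask and intensities together leaves features unchanged."""
        from dosiomics.preprocess import PreprocessedPatient
        base_mask = np.zeros((10, 10, 10))
        base_mask[3:7, 3:7, 3:7] = 1.0
        vals = np.full((10, 10, 10), np.nan)
        vals[3:7, 3:7, 3:7] = rng.uniform(size=(4, 4, 4))
        shift = (2, 1, -2)
        mask_b = np.roll(base_mask, shift, axis=(0, 1, 2))
        vals_b = np.roll(vals, shift, axis=(0, 1, 2))

        def bundle(mask, values):
            m = RoiMask(mask, (1, 1, 1))
            pre = PreprocessedPatient("t", m)
            from dosiomics.preprocess import discretize_fbn
            for mod in ("CT", "PET", "BED"):
                vol = _masked(values)
                pre.masked[mod] = vol
                pre.discretized[mod] = discretize_fbn(vol, 16)
            return pre

        va = extract_all(bundle(base_mask, vals), 16)
        vb = extract_all(bundle(mask_b, vals_b), 16)
        np.testing.assert_allclose(va.values, vb.values, rtol=1e-5)
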