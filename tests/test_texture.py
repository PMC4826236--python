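import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromatex import GLCMParams, GLCMatrix, ImageGrid, LabelMask
from chromatex.texture import (PATTERN_ASSOCIATIONS, compute_glcm, haralick_features,
                               interpret_chromatin_pattern, nucleus_texture_profile,
                               percent_change, quantize, roi_texture)
from conftest import glcm_bruteforce


class TestQuantize:
    def test_identity_binning_at_256(self, rng):
        img = ImageGrid(rng.integers(0, 256, size=(16, 16)))
        lev = quantize(img, None, 256)
        np.testing.assert_array_equal(lev, img.values)

    def test_two_levels(self):
        img = ImageGrid(np.array([[0, 255], [255, 0]]))
        assert set(np.unique(quantize(img, None, 2))) == {0, 1}

    def test_uniform_bin_width(self, rng):
        img = ImageGrid(rng.integers(0, 256, size=(64, 64)))
        lev = quantize(img, None, 8)
        # every bin spans exactly 32 grey values
        for g in range(8):
            vals = img.values[lev == g]
            if vals.size:
                assert vals.min() >= 32 * g and vals.max() < 32 * (g + 1)

    def test_mask_sentinel_and_empty_mask(self, rng):
        img = ImageGrid(rng.integers(0, 256, size=(8, 8)))
        mask = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError):
            quantize(img, mask, 8)
        mask[2, 2] = True
        lev = quantize(img, mask, 8)
        assert (lev[~mask] == -1).all() and lev[2, 2] >= 0


class TestGLCM:
    def test_constant_grid_single_cell(self):
        lev = np.full((4, 4), 5, dtype=np.int32)
        (g,) = compute_glcm(lev, GLCMParams(levels=32, angles=(0,)))
        assert g.p[5, 5] == 1.0 and g.p.sum() == 1.0

    def test_checkerboard_row(self):
        lev = np.array([[0, 1, 0, 1]], dtype=np.int32)
        (g,) = compute_glcm(lev, GLCMParams(levels=2, angles=(0,)))
        assert g.p[0, 1] == pytest.approx(0.5) and g.p[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_bruteforce_oracle(self, rng, symmetric):
        params_base = dict(levels=8, distance=1)
        for _ in range(15):
            lev = rng.integers(0, 8, size=(16, 16)).astype(np.int32)
            valid = np.ones_like(lev, dtype=bool)
            glcms = compute_glcm(lev, GLCMParams(**params_base, symmetric=symmetric))
            for g in glcms:
                oracle = glcm_bruteforce(lev, valid, 8, 1, g.angle, symmetric)
                np.testing.assert_allclose(g.p, oracle, atol=1e-12)

    def test_masked_pixels_excluded(self, rng):
        lev = rng.integers(0, 4, size=(10, 10)).astype(np.int32)
        mask = rng.random((10, 10)) > 0.4
        lev_masked = lev.copy()
        lev_masked[~mask] = -1
        glcms = compute_glcm(lev_masked, GLCMParams(levels=4, symmetric=True))
        for g in glcms:
            oracle = glcm_bruteforce(lev, mask, 4, 1, g.angle, True)
            np.testing.assert_allclose(g.p, oracle, atol=1e-12)

    def test_symmetry_and_normalisation(self, rng):
        lev = rng.integers(0, 6, size=(12, 12)).astype(np.int32)
        for g in compute_glcm(lev, GLCMParams(levels=6, symmetric=True)):
            np.testing.assert_allclose(g.p, g.p.T, atol=1e-15)
            assert g.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_small_roi_raises(self):
        lev = np.array([[1]], dtype=np.int32)
        with pytest.raises(ValueError):
            compute_glcm(lev, GLCMParams(levels=2, angles=(0,)))


def _single_cell_glcm(levels=4, k=2):
    p = np.zeros((levels, levels))
    p[k, k] = 1.0
    return GLCMatrix(p, GLCMParams(levels=levels, angles=(0,)), 0, 10)


class TestHaralickFeatures:
    def test_single_cell_closed_form(self):
        f = haralick_features(_single_cell_glcm())
        assert (f.asm, f.contrast, f.idm, f.entropy) == (1.0, 0.0, 1.0, 0.0)
        assert not f.correlation_defined and math.isnan(f.correlation)

    def test_checkerboard_closed_form(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(GLCMatrix(p, GLCMParams(levels=2, angles=(0,)), 0, 4))
        assert f.asm == pytest.approx(0.5)
        assert f.contrast == pytest.approx(1.0)
        assert f.idm == pytest.approx(0.5)
        assert f.entropy == pytest.approx(1.0)
        assert f.correlation == pytest.approx(-1.0)

    def test_uniform_two_level_closed_form(self):
        p = np.full((2, 2), 0.25)
        f = haralick_features(GLCMatrix(p, GLCMParams(levels=2, angles=(0,)), 0, 4))
        assert f.asm == pytest.approx(0.25)
        assert f.contrast == pytest.approx(0.5)
        assert f.idm == pytest.approx(0.75)
        assert f.entropy == pytest.approx(2.0)
        assert f.correlation == pytest.approx(0.0)

    def test_angle_averaging_skips_undefined_correlation(self):
        defined = GLCMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]),
                            GLCMParams(levels=2, angles=(0,)), 0, 4)
        undefined = _single_cell_glcm(levels=2, k=1)
        f = haralick_features([defined, undefined])
        assert f.correlation_defined
        assert f.correlation == pytest.approx(-1.0)  # averaged over the one defined angle
        assert f.asm == pytest.approx((0.5 + 1.0) / 2)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_feature_bounds(self, seed):
        rng = np.random.default_rng(seed)
        lev = rng.integers(0, 8, size=(12, 12)).astype(np.int32)
        f = haralick_features(compute_glcm(lev, GLCMParams(levels=8)))
        assert 0 < f.asm <= 1 and 0 < f.idm <= 1
        assert f.contrast >= 0
        assert 0 <= f.entropy <= 2 * math.log2(8) + 1e-12
        if f.correlation_defined:
            assert -1 <= f.correlation <= 1

    def test_gain_invariance_within_bins(self):
        # gain 1.5 keeps 40 in the lower and 150 in the upper of 2 bins,
        # so a pure intensity gain leaves the co-occurrence pattern alone
        base = np.array([[40, 40, 150, 150]] * 4, dtype=np.int64)
        img1 = ImageGrid(base)
        img2 = ImageGrid(base * 3 // 2)
        p = GLCMParams(levels=2, angles=(0,))
        f1 = haralick_features(compute_glcm(quantize(img1, None, 2), p))
        f2 = haralick_features(compute_glcm(quantize(img2, None, 2), p))
        assert f1 == f2


class TestNucleusProfile:
    def test_constant_interior_nucleus_matches_closed_form(self):
        img = np.zeros((20, 20), dtype=np.int64)
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[4:16, 4:16] = 1
        img[labels == 1] = 128
        table, means = nucleus_texture_profile(ImageGrid(img), LabelMask(labels),
                                               GLCMParams())
        row = table.iloc[0]
        assert (row.asm, row.contrast, row.idm, row.entropy) == (1.0, 0.0, 1.0, 0.0)
        assert not row.correlation_defined
        assert means["n_correlation_undefined"] == 1

    def test_identical_stamped_nuclei_zero_sd(self, rng):
        patch = rng.integers(0, 256, size=(10, 10))
        img = np.zeros((40, 40), dtype=np.int64)
        labels = np.zeros((40, 40), dtype=np.int32)
        for i, (r, c) in enumerate([(2, 2), (2, 22), (22, 2), (22, 22)], start=1):
            img[r:r + 10, c:c + 10] = patch
            labels[r:r + 10, c:c + 10] = i
        table, _ = nucleus_texture_profile(ImageGrid(img), LabelMask(labels),
                                           GLCMParams(), boundary_erosion_px=0)
        for feat in ("asm", "contrast", "idm", "entropy"):
            assert table[feat].std() == pytest.approx(0.0, abs=1e-12)

    def test_zero_nuclei_empty_table(self):
        img = ImageGrid(np.zeros((10, 10), dtype=np.int64))
        table, means = nucleus_texture_profile(img, LabelMask(np.zeros((10, 10), dtype=np.int32)),
                                               GLCMParams())
        assert table.empty
        assert means["asm"] is None


class TestPercentChange:
    @pytest.mark.parametrize("control,treated,expected", [
        (0.20, 0.20, 0.0),
        (0.20, 0.16, -20.0),
        (0.10, 0.14, 40.0),
    ])
    def test_arithmetic(self, control, treated, expected):
        out = percent_change({"asm": treated}, {"asm": control}, features=("asm",))
        assert out["asm"] == pytest.approx(expected)

    def test_zero_control_flagged(self):
        out = percent_change({"asm": 0.1}, {"asm": 0.0}, features=("asm",))
        assert math.isnan(out["asm"])


class TestPatternInterpretation:
    def test_platinum_like_signature(self):
        # directions seen after DNA-damaging treatment: ASM/corr/IDM down,
        # entropy/contrast up -> less homogeneous, more heterogeneous/contrasted
        changes = {"asm": -20, "correlation": -25, "entropy": 6, "idm": -15, "contrast": 40}
        call = interpret_chromatin_pattern(changes)
        assert call.homogeneity == "decreased"
        assert call.heterogeneity == "increased"
        assert call.contrast_pattern == "increased"

    def test_hdac_inhibition_like_signature_reverses(self):
        changes = {"asm": 15, "correlation": 20, "entropy": -10, "idm": 12, "contrast": -30}
        call = interpret_chromatin_pattern(changes)
        assert call.homogeneity == "increased"
        assert call.heterogeneity == "decreased"
        assert call.contrast_pattern == "decreased"

    def test_all_zero_changes_unchanged(self):
        call = interpret_chromatin_pattern({f: 0.0 for f in
                                            ("asm", "correlation", "entropy", "idm", "contrast")})
        assert (call.homogeneity, call.heterogeneity, call.contrast_pattern) == (
            "unchanged", "unchanged", "unchanged")

    def test_conflicting_votes_indeterminate(self):
        # entropy says homogeneity down, ASM/IDM say up
        call = interpret_chromatin_pattern({"asm": 20, "idm": 20, "entropy": 20,
                                            "correlation": 0, "contrast": 0})
        assert call.homogeneity == "indeterminate"

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            interpret_chromatin_pattern({"asm": float("nan")})

    def test_association_map_covers_all_patterns(self):
        assert set(PATTERN_ASSOCIATIONS) == {"homogeneity", "heterogeneity", "contrast"}
        for assoc in PATTERN_ASSOCIATIONS.values():
            assert len(assoc) >= 2
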