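"""Texture features against brute-force enumeration references."""

import numpy as np
import pytest
import pywt

from oracles import (
    bf_discretize,
    bf_firstorder,
    bf_glcm,
    bf_gldm_ldlgle,
    bf_glszm,
    bf_wavelet_band,
)
from conftest import random_masked_grid, random_roi
from trusrad.catalog import parse_key
from trusrad.texture import (
    SELECTED_FEATURE_KEYS,
    DiscretizationConfig,
    ExtractionConfig,
    compute_descriptor,
    discretize,
    extract_selected,
    firstorder_features,
    glcm_features,
    gldm_feature,
    glszm_features,
    wavelet_decompose,
)
from trusrad.volumes import ROIVolume


# ---------------------------------------------------------------------------
# wavelet
# ---------------------------------------------------------------------------

class TestWavelet:
    def test_constant_input(self):
        bands = wavelet_decompose(np.full((8, 9, 10), 5.0), "coif1")
        assert np.allclose(bands["LLL"], bands["LLL"].flat[0])
        for key, band in bands.items():
            assert band.shape == (8, 9, 10)
            if "H" in key:
                assert np.allclose(band, 0.0, atol=1e-10)

    def test_impulse_matches_separable_filter_response(self, rng):
        vol = np.zeros((6, 7, 8))
        vol[2, 3, 4] = 1.0
        wav = pywt.Wavelet("haar")
        filt = {"L": np.array(wav.dec_lo), "H": np.array(wav.dec_hi)}
        bands = wavelet_decompose(vol, "haar")
        for key, band in bands.items():
            ref = bf_wavelet_band(vol, [filt[c] for c in key])
            np.testing.assert_allclose(band, ref, atol=1e-12)

    @pytest.mark.parametrize("wavelet", ["haar", "coif1", "db2"])
    def test_random_volume_matches_bruteforce(self, rng, wavelet):
        wav = pywt.Wavelet(wavelet)
        extent = max(8, len(wav.dec_lo))
        vol = rng.standard_normal((extent, extent, extent))
        filt = {"L": np.array(wav.dec_lo), "H": np.array(wav.dec_hi)}
        bands = wavelet_decompose(vol, wavelet)
        assert set(bands) == {a + b + c for a in "LH" for b in "LH" for c in "LH"}
        for key in ("LLL", "HLH", "HHH"):
            ref = bf_wavelet_band(vol, [filt[c] for c in key])
            np.testing.assert_allclose(bands[key], ref, atol=1e-10)

    def test_too_small_volume_names_axis(self):
        with pytest.raises(ValueError, match="axis 1"):
            wavelet_decompose(np.zeros((8, 3, 8)), "coif1")


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_hand_case(self):
        vol = np.array([0, 24.9, 25, 100.0]).reshape(1, 1, 4)
        mask = np.ones_like(vol, bool)
        levels, ng = discretize(vol, mask, DiscretizationConfig(25))
        assert levels.ravel().tolist() == [1, 1, 2, 5]
        assert ng == 5

    def test_wide_bin_collapses_to_one_level(self):
        vol = np.arange(8.0).reshape(2, 2, 2)
        levels, ng = discretize(vol, np.ones((2, 2, 2), bool),
                                DiscretizationConfig(100.0))
        assert ng == 1 and set(levels.ravel()) == {1}

    def test_shift_invariance(self, rng):
        vol = rng.random((4, 4, 4)) * 100
        mask = rng.random((4, 4, 4)) < 0.6
        mask.flat[:2] = True
        l1, _ = discretize(vol, mask)
        l2, _ = discretize(vol + 123.4, mask)
        np.testing.assert_array_equal(l1, l2)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            vol = rng.random((3, 4, 5)) * 300
            mask = rng.random((3, 4, 5)) < 0.5
            mask.flat[:2] = True
            levels, ng = discretize(vol, mask, DiscretizationConfig(17.0))
            ref, ref_ng = bf_discretize(vol, mask, 17.0)
            np.testing.assert_array_equal(levels, ref)
            assert ng == ref_ng


# ---------------------------------------------------------------------------
# GLCM / GLSZM / GLDM / first-order
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_checkerboard_slab_matches_pair_enumeration(self):
        levels = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        mask = np.ones((4, 4, 1), bool)
        got = glcm_features(levels, mask)
        ref = bf_glcm(levels, mask)
        for k in got:
            assert got[k] == pytest.approx(ref[k], abs=1e-12)

    def test_constant_roi_closed_forms(self):
        levels = np.where(np.ones((3, 3, 3), bool), 1, 0)
        got = glcm_features(levels, np.ones((3, 3, 3), bool))
        assert got["ClusterShade"] == 0.0
        assert got["ClusterProminence"] == 0.0
        assert got["Correlation"] == 1.0

    def test_translation_invariance(self, rng):
        levels, mask = random_masked_grid(rng, max_extent=4)
        big_l = np.zeros((9, 9, 9), dtype=np.int64)
        big_m = np.zeros((9, 9, 9), dtype=bool)
        sl = tuple(slice(2, 2 + s) for s in levels.shape)
        big_l[sl], big_m[sl] = levels, mask
        assert glcm_features(levels, mask) == glcm_features(big_l, big_m)

    def test_random_grids_match_bruteforce(self, rng):
        for _ in range(30):
            levels, mask = random_masked_grid(rng)
            got = glcm_features(levels, mask)
            ref = bf_glcm(levels, mask)
            for k in got:
                assert got[k] == pytest.approx(ref[k], abs=1e-9), k


class TestGLSZM:
    def test_single_zone_closed_forms(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), bool)
        levels[0, :, 0] = 3
        mask[0, :, 0] = True          # one zone, level 3, size 3
        got = glszm_features(levels, mask)
        assert got["ZoneEntropy"] == pytest.approx(0.0)
        assert got["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert got["LargeAreaHighGrayLevelEmphasis"] == pytest.approx(81.0)
        assert got["SizeZoneNonUniformityNormalized"] == pytest.approx(1.0)
        assert got["SmallAreaHighGrayLevelEmphasis"] == pytest.approx(1.0)

    def test_three_zone_slab_matches_flood_fill(self):
        levels = np.array([[1, 1, 2, 2],
                           [1, 1, 2, 2],
                           [3, 3, 3, 3],
                           [1, 1, 1, 1]]).reshape(4, 4, 1)
        mask = np.ones((4, 4, 1), bool)
        got = glszm_features(levels, mask)
        ref = bf_glszm(levels, mask)
        for k in got:
            assert got[k] == pytest.approx(ref[k], abs=1e-12), k

    def test_zone_relabelling_invariance(self):
        # two equal-size zones of the same level at different positions
        a = np.zeros((5, 1, 1), dtype=np.int64)
        a[[0, 3], 0, 0] = 2
        b = np.zeros((5, 1, 1), dtype=np.int64)
        b[[1, 4], 0, 0] = 2
        ma, mb = a > 0, b > 0
        assert glszm_features(a, ma) == glszm_features(b, mb)

    def test_random_grids_match_bruteforce(self, rng):
        for connectivity in (26, 6):
            for _ in range(15):
                levels, mask = random_masked_grid(rng)
                got = glszm_features(levels, mask, connectivity)
                ref = bf_glszm(levels, mask, connectivity)
                for k in got:
                    assert got[k] == pytest.approx(ref[k], abs=1e-9), k


class TestGLDM:
    def test_constant_cube_center_dependence(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), bool)
        got = gldm_feature(levels, mask, alpha=0)
        assert got == pytest.approx(bf_gldm_ldlgle(levels, mask, 0))

    def test_isolated_voxels_have_unit_dependence(self):
        # two far-apart level-1 voxels: d = 1 each, LDLGLE = 1
        levels = np.zeros((5, 5, 5), dtype=np.int64)
        mask = np.zeros((5, 5, 5), bool)
        levels[0, 0, 0] = levels[4, 4, 4] = 1
        mask[0, 0, 0] = mask[4, 4, 4] = True
        assert gldm_feature(levels, mask) == pytest.approx(1.0)

    def test_raising_levels_decreases_value(self, rng):
        levels, mask = random_masked_grid(rng)
        assert gldm_feature(levels * 2, mask) < gldm_feature(levels, mask)

    def test_random_grids_match_bruteforce(self, rng):
        for alpha in (0.0, 1.0):
            for _ in range(15):
                levels, mask = random_masked_grid(rng)
                got = gldm_feature(levels, mask, alpha)
                assert got == pytest.approx(bf_gldm_ldlgle(levels, mask, alpha))


class TestFirstOrder:
    def test_hand_cases(self):
        vol = np.array([1.0, 5.0, 3.0]).reshape(1, 1, 3)
        got = firstorder_features(vol, np.ones((1, 1, 3), bool))
        assert got["Range"] == 4.0 and got["Median"] == 3.0

        sym = np.array([-2.0, -1, 0, 1, 2]).reshape(1, 1, 5)
        assert firstorder_features(sym, np.ones((1, 1, 5), bool))["Skewness"] == \
            pytest.approx(0.0)

    def test_skewed_sample_matches_moment_formula(self):
        vol = np.array([0.0, 0, 0, 0, 10]).reshape(1, 1, 5)
        mask = np.ones((1, 1, 5), bool)
        got = firstorder_features(vol, mask)
        ref = bf_firstorder(vol, mask)
        assert got["Skewness"] == pytest.approx(ref["Skewness"])
        # closed form for {0,0,0,0,10}: m2=16, m3=96 -> 96/64 = 1.5
        assert got["Skewness"] == pytest.approx(1.5)

    def test_zero_variance_skewness_defined_zero(self):
        vol = np.full((2, 2, 2), 7.0)
        got = firstorder_features(vol, np.ones((2, 2, 2), bool))
        assert got["Skewness"] == 0.0 and got["Range"] == 0.0


# ---------------------------------------------------------------------------
# signature extraction
# ---------------------------------------------------------------------------

class TestExtractSelected:
    CFG = ExtractionConfig(bin_width=25.0, wavelet="haar")

    def _oracle(self, roi):
        import pywt as _pywt

        wav = _pywt.Wavelet("haar")
        filt = {"L": np.array(wav.dec_lo), "H": np.array(wav.dec_hi)}
        out = {}
        for key in SELECTED_FEATURE_KEYS:
            desc = parse_key(key)
            if desc.image_type == "original":
                img = roi.intensities
            else:
                band = desc.image_type.split("-")[1]
                img = bf_wavelet_band(roi.intensities, [filt[c] for c in band])
            if desc.feature_class == "firstorder":
                out[key] = bf_firstorder(img, roi.mask)[desc.name]
            else:
                levels, _ = bf_discretize(img, roi.mask, 25.0)
                if desc.feature_class == "glcm":
                    out[key] = bf_glcm(levels, roi.mask)[desc.name]
                elif desc.feature_class == "glszm":
                    out[key] = bf_glszm(levels, roi.mask)[desc.name]
                else:
                    out[key] = bf_gldm_ldlgle(levels, roi.mask, 0.0)
        return out

    def test_returns_all_14_keys_deterministically(self, rng):
        roi = random_roi(rng)
        v1 = extract_selected(roi, self.CFG)
        v2 = extract_selected(ROIVolume(roi.intensities.copy(), roi.mask.copy()),
                              self.CFG)
        assert list(v1) == list(SELECTED_FEATURE_KEYS)
        assert v1 == v2

    def test_tiny_phantom_matches_bruteforce(self, rng):
        roi = random_roi(rng, extent=4)
        got = extract_selected(roi, self.CFG)
        ref = self._oracle(roi)
        for key in SELECTED_FEATURE_KEYS:
            assert got[key] == pytest.approx(ref[key], rel=1e-9, abs=1e-9), key

    def test_axis_rotation_preserves_glszm_features(self, rng):
        vol = rng.random((5, 5, 5)) * 200
        mask = rng.random((5, 5, 5)) < 0.7
        mask.flat[:4] = True
        levels, _ = discretize(vol, mask)
        rot_l = np.rot90(levels, k=1, axes=(0, 1))
        rot_m = np.rot90(mask, k=1, axes=(0, 1))
        assert glszm_features(levels, mask) == glszm_features(rot_l, rot_m)

    def test_unimplemented_catalog_descriptor_raises(self, rng):
        roi = random_roi(rng)
        desc = parse_key("original_ngtdm_Busyness")
        with pytest.raises(NotImplementedError, match="no numeric implementation"):
            compute_descriptor(desc, roi.intensities, roi.mask, self.CFG)

    def test_mask_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ROIVolume(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))
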