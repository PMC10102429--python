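"""GLCM construction and Haralick statistics against independent oracles."""
import numpy as np
import pytest
from skimage.feature import graycomatrix

from conftest import brute_glcm, brute_haralick
from texlai.errors import DomainError, EmptyROIError
from texlai.texture import (DEFAULT_OFFSETS, GLCMConfig, STAT_NAMES, glcm,
                            haralick_stats, quantize, roi_texture_means,
                            texture_maps)


class TestQuantize:
    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(quantize(np.full((5, 5), 3.3), 8), 0)

    def test_binary_two_levels(self):
        arr = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(quantize(arr, 2), arr.astype(int))

    def test_extremes_hit_first_and_last_level(self):
        rng = np.random.default_rng(1)
        arr = rng.random((10, 10))
        q = quantize(arr, 16)
        assert q[np.unravel_index(arr.argmin(), arr.shape)] == 0
        assert q[np.unravel_index(arr.argmax(), arr.shape)] == 15

    def test_order_preserving(self):
        rng = np.random.default_rng(2)
        arr = rng.random(100).reshape(10, 10)
        q = quantize(arr, 6)
        order = np.argsort(arr, axis=None)
        assert np.all(np.diff(q.ravel()[order]) >= 0)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.full((3, 3), np.nan), 4)


class TestGLCM:
    def test_constant_window_single_entry(self):
        P = glcm(np.zeros((3, 3), dtype=int), (0, 1), 4, symmetric=True)
        assert P[0, 0] == 1.0
        assert P.sum() == 1.0

    def test_checkerboard_closed_form(self):
        cb = np.indices((4, 4)).sum(axis=0) % 2
        P = glcm(cb, (0, 1), 2, symmetric=True)
        np.testing.assert_allclose(P, [[0, 0.5], [0.5, 0]])

    @pytest.mark.parametrize("offset", DEFAULT_OFFSETS)
    def test_matches_pair_enumeration_oracle(self, offset):
        rng = np.random.default_rng(3)
        for trial in range(10):
            win = rng.integers(0, 6, size=(5, 5))
            P = glcm(win, offset, 6, symmetric=True)
            np.testing.assert_allclose(
                P, brute_glcm(win, [offset], 6, True), atol=1e-12
            )

    def test_matches_skimage(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        ours = glcm(img, (0, 1), 8, symmetric=True)
        ref = graycomatrix(img, [1], [0], levels=8, symmetric=True,
                           normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_symmetry_contract(self):
        rng = np.random.default_rng(5)
        win = rng.integers(0, 4, size=(6, 6))
        P = glcm(win, (1, -1), 4, symmetric=True)
        np.testing.assert_allclose(P, P.T)

    def test_no_valid_pairs(self):
        with pytest.raises(DomainError):
            glcm(np.full((2, 2), -1), (0, 1), 4, True)


class TestHaralickStats:
    def test_degenerate_single_entry(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        s = haralick_stats(P)
        assert s["con"] == 0 and s["dis"] == 0 and s["var"] == 0
        assert s["hom"] == 1 and s["ent"] == 0 and s["sm"] == 1
        assert s["cor"] == 0.0  # zero marginal variance convention
        assert s["mean"] == 2.0

    def test_checkerboard_closed_forms(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        s = haralick_stats(P)
        assert s["mean"] == pytest.approx(0.5)
        assert s["var"] == pytest.approx(0.25)
        assert s["con"] == pytest.approx(1.0)
        assert s["dis"] == pytest.approx(1.0)
        assert s["hom"] == pytest.approx(0.5)
        assert s["ent"] == pytest.approx(np.log(2))
        assert s["sm"] == pytest.approx(0.5)
        assert s["cor"] == pytest.approx(-1.0)

    def test_uniform_glcm_closed_forms(self):
        for L in (2, 4, 8):
            P = np.full((L, L), 1.0 / L**2)
            s = haralick_stats(P)
            assert s["sm"] == pytest.approx(1.0 / L**2)
            assert s["ent"] == pytest.approx(2 * np.log(L))
            assert s["cor"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_defining_sums_on_random_glcms(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            C = rng.random((5, 5))
            C = C + C.T
            P = C / C.sum()
            ours = haralick_stats(P)
            ref = brute_haralick(P)
            for k in STAT_NAMES:
                assert ours[k] == pytest.approx(ref[k], abs=1e-12), k


class TestTextureMaps:
    def test_constant_raster_zero_contrast(self):
        maps = texture_maps(np.full((8, 8), 0.7), GLCMConfig(levels=8))
        interior = maps["con"][1:-1, 1:-1]
        np.testing.assert_array_equal(interior, 0.0)
        assert np.isnan(maps["con"][0, 0])  # border flagged missing

    def test_oracle_equivalence_on_random_fixture(self):
        """Interior map values equal direct per-window GLCM recomputation."""
        rng = np.random.default_rng(7)
        arr = rng.random((12, 12))
        for cfg in (
            GLCMConfig(levels=8, window=3),
            GLCMConfig(levels=4, window=5, offsets=((0, 1), (1, -1))),
            GLCMConfig(levels=8, window=3, symmetric=False,
                       offsets=((0, 1), (1, 0))),
        ):
            maps = texture_maps(arr, cfg)
            q = quantize(arr, cfg.levels)
            h = cfg.window // 2
            for cr in range(h, 12 - h):
                for cc in range(h, 12 - h):
                    win = q[cr - h : cr + h + 1, cc - h : cc + h + 1]
                    P = brute_glcm(win, cfg.offsets, cfg.levels, cfg.symmetric)
                    ref = brute_haralick(P)
                    for k in STAT_NAMES:
                        assert maps[k][cr, cc] == pytest.approx(
                            ref[k], abs=1e-9
                        ), (k, cr, cc)

    def test_bounds_hold_on_noise(self):
        rng = np.random.default_rng(8)
        maps = texture_maps(rng.random((16, 16)), GLCMConfig(levels=16))
        inner = {k: v[1:-1, 1:-1] for k, v in maps.items()}
        assert np.all((inner["hom"] > 0) & (inner["hom"] <= 1))
        assert np.all((inner["sm"] > 0) & (inner["sm"] <= 1))
        assert np.all(inner["ent"] >= 0)
        assert np.all(inner["con"] >= 0)
        assert np.all((inner["cor"] >= -1) & (inner["cor"] <= 1))

    def test_larger_window_smooths_contrast(self):
        # contrast map varies less across pixels with a larger window
        cfg3, cfg7 = GLCMConfig(window=3), GLCMConfig(window=7)
        spread3, spread7 = [], []
        for s in range(20):
            arr = np.random.default_rng(s).random((20, 20))
            m3 = texture_maps(arr, cfg3)["con"]
            m7 = texture_maps(arr, cfg7)["con"]
            spread3.append(np.nanvar(m3))
            spread7.append(np.nanvar(m7))
        assert np.mean(spread7) < np.mean(spread3)

    def test_raster_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            texture_maps(np.zeros((2, 4)), GLCMConfig())


class TestRoiTextureMeans:
    def test_24_named_values_for_three_bands(self):
        rng = np.random.default_rng(9)
        cfg = GLCMConfig(levels=8)
        maps = {
            b: texture_maps(rng.random((10, 10)), cfg) for b in (650, 705, 842)
        }
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        vals = roi_texture_means(maps, mask)
        assert len(vals) == 24
        assert "ent_705" in vals and "con_842" in vals and "mean_650" in vals

    def test_constant_band_zero_contrast_mean(self):
        cfg = GLCMConfig(levels=8)
        maps = {650: texture_maps(np.full((10, 10), 0.5), cfg)}
        mask = np.ones((10, 10), dtype=bool)
        vals = roi_texture_means(maps, mask)
        assert vals["con_650"] == 0.0

    def test_matches_masked_nanmean_oracle(self):
        rng = np.random.default_rng(10)
        cfg = GLCMConfig(levels=8)
        raster = rng.random((12, 12))
        maps = {842: texture_maps(raster, cfg)}
        mask = rng.random((12, 12)) > 0.5
        vals = roi_texture_means(maps, mask)
        m = maps["842"] if "842" in maps else maps[842]
        for stat in STAT_NAMES:
            sel = m[stat][mask]
            assert vals[f"{stat}_842"] == pytest.approx(
                np.nanmean(sel[np.isfinite(sel)])
            )

    def test_border_only_roi_rejected(self):
        cfg = GLCMConfig()
        maps = {650: texture_maps(np.random.default_rng(0).random((8, 8)), cfg)}
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :] = True  # only border pixels
        with pytest.raises(EmptyROIError):
            roi_texture_means(maps, mask)

    def test_empty_mask_rejected(self):
        cfg = GLCMConfig()
        maps = {650: texture_maps(np.zeros((8, 8)), cfg)}
        with pytest.raises(EmptyROIError):
            roi_texture_means(maps, np.zeros((8, 8), dtype=bool))
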