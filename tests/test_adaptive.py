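"""2D linear-prediction detector: gamma map, thresholding, region growing."""

import numpy as np
import pytest

from mammocad import (GrayImage, LatticeConfig, detect_microcalcifications,
                      predict_errors, region_grow)
from mammocad.errors import ConfigurationError, ParameterError
from .conftest import flat_image


def oracle_gamma(x, cfg):
    """Pixel-by-pixel normal-equation solve, coded independently: for each
    valid pixel, the same windowed second moments, ridge and gamma formula,
    but assembled with explicit loops over window means."""
    x = np.asarray(x, float)
    m_r, m_c = cfg.region_rows - 1, cfg.region_cols - 1
    half = cfg.train_window // 2
    offsets_f = [(di, dj) for di in range(cfg.region_rows)
                 for dj in range(cfg.region_cols) if (di, dj) != (0, 0)]
    p = len(offsets_f)
    gamma = np.ones_like(x)
    top, left = m_r + half, m_c + half
    for r in range(top, x.shape[0] - top):
        for c in range(left, x.shape[1] - left):
            errs = []
            for sgn in (+1, -1):
                offs = [(sgn * di, sgn * dj) for (di, dj) in offsets_f]
                rows = np.arange(r - half, r + half + 1)
                cols = np.arange(c - half, c + half + 1)
                rr, cc = np.meshgrid(rows, cols, indexing="ij")
                target = x[rr, cc].ravel()
                design = np.stack([x[rr - di, cc - dj].ravel() for (di, dj) in offs], axis=1)
                A = design.T @ design / target.size
                b = design.T @ target / target.size
                A = A + np.eye(p) * (cfg.ridge * np.trace(A) / p)
                a = np.linalg.solve(A, b)
                x_hat = sum(a[k] * x[r - offs[k][0], c - offs[k][1]] for k in range(p))
                errs.append(x[r, c] - x_hat)
            rel = 0.5 * (errs[0] ** 2 + errs[1] ** 2) / x[r, c] ** 2
            if rel < 1e-10:
                rel = 0.0
            gamma[r, c] = min(max(1.0 - rel, 0.0), 1.0)
    return gamma


class TestPredictErrors:
    def test_constant_image_perfectly_stationary(self):
        gm = predict_errors(flat_image(100.0, (48, 48)))
        assert np.all(gm.gamma == 1.0)
        # the ridge stabiliser leaves O(ridge)-sized prediction residue
        assert np.allclose(gm.forward_error, 0.0, atol=1e-3)
        assert np.allclose(gm.backward_error, 0.0, atol=1e-3)

    def test_linear_ramp_perfectly_predictable(self):
        px = np.add.outer(np.arange(48) * 2.0, np.arange(48) * 3.0) + 50.0
        gm = predict_errors(GrayImage(pixels=px, bit_depth=16))
        assert gm.gamma.min() > 0.999999

    def test_white_noise_matches_pixelwise_oracle(self, rng):
        x = rng.uniform(50, 150, (40, 40))
        cfg = LatticeConfig(train_window=9)
        gm = predict_errors(GrayImage(pixels=x, bit_depth=8), cfg)
        ref = oracle_gamma(x, cfg)
        assert abs(gm.gamma.mean() - ref.mean()) < 1e-8
        assert np.allclose(gm.gamma, ref, atol=1e-8)
        # noise is unpredictable: gamma strictly below 1 on the interior
        interior = gm.gamma[11:-11, 11:-11]
        assert (interior < 1.0).mean() > 0.99

    def test_hot_pixel_minimizes_gamma_nearby(self):
        px = np.full((48, 48), 100.0)
        px[24, 24] = 4000.0
        gm = predict_errors(GrayImage(pixels=px, bit_depth=12))
        # the global minimum value is attained inside the 3x3 neighbourhood
        # (clamping at 0 ties it with dependent pixels a little further out)
        assert gm.gamma[23:26, 23:26].min() == gm.gamma.min()
        assert gm.gamma.min() < 0.5

    def test_gamma_bounded(self, rng):
        x = rng.uniform(1, 4000, (40, 40))
        gm = predict_errors(GrayImage(pixels=x, bit_depth=12))
        assert gm.gamma.min() >= 0.0 and gm.gamma.max() <= 1.0

    def test_border_never_scored(self, rng):
        gm = predict_errors(GrayImage(pixels=rng.uniform(1, 255, (40, 40)), bit_depth=8))
        assert np.all(gm.gamma[:9, :] == 1.0) and np.all(gm.gamma[:, :9] == 1.0)
        assert np.all(gm.gamma[-9:, :] == 1.0) and np.all(gm.gamma[:, -9:] == 1.0)

    def test_window_must_fit(self):
        with pytest.raises(ConfigurationError):
            predict_errors(flat_image(shape=(10, 10)), LatticeConfig(train_window=15))


class TestDetect:
    def test_constant_image_yields_nothing(self):
        assert detect_microcalcifications(flat_image(100.0, (48, 48))) == []

    def test_small_footprint_discarded_by_five_pixel_rule(self):
        px = np.full((64, 64), 100.0)
        px[32, 32] += 100.0  # low-gamma footprint of 1 px
        img = GrayImage(pixels=px, bit_depth=8)
        assert (predict_errors(img).gamma < 0.90).sum() < 5
        assert detect_microcalcifications(img) == []

    def test_block_discontinuity_detected_as_single_roi(self):
        px = np.full((64, 64), 100.0)
        px[31:34, 31:34] += 400.0
        rois = detect_microcalcifications(GrayImage(pixels=px, bit_depth=12))
        assert len(rois) == 1
        rmin, cmin, rmax, cmax = rois[0].bbox
        assert rmin <= 32 <= rmax and cmin <= 32 <= cmax

    def test_mask_monotone_in_threshold(self, rng):
        x = rng.uniform(50, 150, (48, 48))
        img = GrayImage(pixels=x, bit_depth=8)
        gm = predict_errors(img)
        low = gm.gamma < 0.80
        high = gm.gamma < 0.95
        assert np.all(high[low])  # raising gamma_0 only grows the mask


class TestRegionGrow:
    def test_empty_mask(self):
        assert region_grow(np.zeros((8, 8), bool), 5, 8) == []

    def test_size_filter_keeps_only_large_blob(self):
        mask = np.zeros((12, 12), bool)
        mask[1:3, 1:3] = True          # 4 px: dropped
        mask[6:9, 6:8] = True          # 6 px: kept
        rois = region_grow(mask, 5, 8)
        assert len(rois) == 1
        assert rois[0].area_px == 6
        assert rois[0].centroid == (7.0, 6.5)

    def test_diagonal_chain_connectivity(self):
        mask = np.zeros((8, 8), bool)
        for i in range(6):
            mask[i, i] = True
        assert len(region_grow(mask, 1, 8)) == 1
        assert len(region_grow(mask, 1, 4)) == 6

    def test_results_sorted_by_area_desc(self):
        mask = np.zeros((20, 20), bool)
        mask[1:3, 1:6] = True    # 10 px
        mask[10:12, 10:13] = True  # 6 px
        areas = [r.area_px for r in region_grow(mask, 1, 8)]
        assert areas == sorted(areas, reverse=True)

    def test_bad_config_rejected(self):
        with pytest.raises(ParameterError):
            LatticeConfig(gamma_threshold=1.5)
        with pytest.raises(ParameterError):
            LatticeConfig(connectivity=6)
        with pytest.raises(ParameterError):
            LatticeConfig(region_rows=1)
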