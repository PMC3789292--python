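"""Fuzzy C-means: update equations, histogram init, hardening, contours."""

import numpy as np
import pytest

from mammocad import (FCMConfig, GrayImage, extract_mass_contour, fcm_fit,
                      hard_segmentation, histogram_init)
from mammocad.errors import DegenerateInputError, DimensionError, ParameterError


def reference_fcm(x, V0, m=2.0, p=2, eps=1e-6, max_iter=200):
    """Literal coordinate-descent iteration, coded independently of the
    library: membership from pairwise distance ratios, centroids from
    fuzzified weighted means, stop on summed centroid displacement."""
    x = np.asarray(x, float)
    V = np.asarray(V0, float).copy()
    c = len(V)
    for _ in range(max_iter):
        U = np.zeros((c, len(x)))
        for k, xk in enumerate(x):
            d = np.array([abs(xk - vi) for vi in V])
            if np.any(d == 0):
                U[np.argmin(d), k] = 1.0
                continue
            for i in range(c):
                U[i, k] = 1.0 / sum((d[i] / d[j]) ** (p / (m - 1)) for j in range(c))
        V_new = np.array([np.sum(U[i] ** m * x) / np.sum(U[i] ** m) for i in range(c)])
        E = np.sum(np.abs(V_new - V))
        V = V_new
        if E < eps:
            break
    # final membership for the final centroids
    U = np.zeros((c, len(x)))
    for k, xk in enumerate(x):
        d = np.array([abs(xk - vi) for vi in V])
        if np.any(d == 0):
            U[np.argmin(d), k] = 1.0
            continue
        for i in range(c):
            U[i, k] = 1.0 / sum((d[i] / d[j]) ** (p / (m - 1)) for j in range(c))
    return U, V


class TestFcmFit:
    def test_points_at_centroids_converge_immediately(self):
        res = fcm_fit([0.0, 10.0], FCMConfig(c=2, V0=[0.0, 10.0]))
        assert res.iterations == 1
        assert np.allclose(res.U, [[1, 0], [0, 1]])
        assert res.J_trace[-1] == 0.0

    def test_symmetric_data_gives_symmetric_centroids(self):
        res = fcm_fit([1, 2, 8, 9], FCMConfig(c=2, V0=[0.0, 10.0]))
        assert res.V[0] + res.V[1] == pytest.approx(10.0, abs=1e-9)

    def test_matches_independent_iteration(self):
        cfg = FCMConfig(c=2, V0=[0.0, 10.0], epsilon=1e-6, max_iter=200)
        res = fcm_fit([1, 2, 8, 9], cfg)
        U_ref, V_ref = reference_fcm([1, 2, 8, 9], [0.0, 10.0], eps=1e-6)
        assert np.allclose(res.V, V_ref, atol=1e-5)
        assert np.allclose(res.U, U_ref, atol=1e-5)

    def test_column_stochastic_and_j_nonincreasing_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            x = rng.uniform(0, 255, n)
            c = int(rng.integers(2, 5))
            v0 = list(np.linspace(x.min() - 1, x.max() + 1, c))
            res = fcm_fit(x, FCMConfig(c=c, V0=v0, epsilon=1e-5))
            assert np.allclose(res.U.sum(axis=0), 1.0, atol=1e-9)
            assert res.U.min() >= 0 and res.U.max() <= 1
            assert np.all(np.diff(res.J_trace) <= 1e-9)

    def test_singularity_rule_one_hot_membership(self):
        res = fcm_fit([0.0, 5.0, 10.0], FCMConfig(c=2, V0=[0.0, 10.0]))
        # sample 0 starts exactly on centroid 0
        first = fcm_fit([0.0, 10.0, 0.0], FCMConfig(c=2, V0=[0.0, 10.0]))
        assert first.U[0, 0] == 1.0 and first.U[1, 0] == 0.0
        assert res.U.shape == (2, 3)

    @pytest.mark.parametrize("m_fuzz", [1.2, 1.5, 2.0, 2.5, 3.0])
    def test_two_spike_convergence_for_any_fuzzifier(self, m_fuzz):
        x = np.array([10.0] * 50 + [200.0] * 50)
        res = fcm_fit(x, FCMConfig(c=2, V0=[50.0, 150.0], m_fuzz=m_fuzz, epsilon=1e-8,
                                   max_iter=500))
        assert sorted(res.V) == pytest.approx([10.0, 200.0], abs=1e-3)

    def test_determinism(self, rng):
        x = rng.uniform(0, 255, 100)
        cfg = FCMConfig(c=3, V0=[10.0, 100.0, 200.0])
        a, b = fcm_fit(x, cfg), fcm_fit(x, cfg)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            fcm_fit([], FCMConfig(c=2, V0=[0.0, 1.0]))
        with pytest.raises(ParameterError):
            FCMConfig(c=2, V0=[5.0, 5.0])  # duplicate initial centroids
        with pytest.raises(ParameterError):
            FCMConfig(c=1, V0=[5.0])


class TestHistogramInit:
    def test_bimodal_spikes(self):
        px = np.concatenate([np.full(5000, 50), np.full(5000, 200)]).reshape(100, 100)
        cfg = histogram_init(GrayImage(pixels=px, bit_depth=8))
        assert cfg.c == 2
        assert cfg.V0 == [50.0, 200.0]

    def test_trimodal_phantom(self):
        px = np.concatenate([np.full(3000, 40), np.full(3000, 120),
                             np.full(3000, 230)]).reshape(90, 100)
        cfg = histogram_init(GrayImage(pixels=px, bit_depth=8))
        assert cfg.c == 3
        assert cfg.V0 == [40.0, 120.0, 230.0]

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            histogram_init(GrayImage(pixels=np.full((10, 10), 7), bit_depth=8))

    def test_c_max_caps_class_count(self):
        px = np.concatenate([np.full(2000, v) for v in (20, 80, 140, 200, 250)]).reshape(100, 100)
        cfg = histogram_init(GrayImage(pixels=px, bit_depth=8), c_max=3)
        assert cfg.c == 3


class TestHardSegmentation:
    def test_argmax_and_tie_break(self):
        from mammocad.fcm import FCMResult
        U = np.array([[0.9, 0.5], [0.1, 0.5]])
        res = FCMResult(U=U, V=np.array([0.0, 1.0]), labels=np.argmax(U, axis=0),
                        J_trace=np.array([0.0]), E_trace=np.array([0.0]), iterations=1)
        out = hard_segmentation(res, (1, 2))
        assert out.tolist() == [[0, 0]]  # 0.9 -> class 0; tie -> lowest index

    def test_matches_exhaustive_argmax(self, rng):
        from mammocad.fcm import FCMResult
        U = rng.uniform(size=(3, 16))
        U /= U.sum(axis=0)
        res = FCMResult(U=U, V=np.zeros(3), labels=np.argmax(U, axis=0),
                        J_trace=np.array([0.0]), E_trace=np.array([0.0]), iterations=1)
        out = hard_segmentation(res, (4, 4))
        expected = np.array([[np.argmax(U[:, r * 4 + c]) for c in range(4)] for r in range(4)])
        assert np.array_equal(out, expected)

    def test_shape_mismatch(self):
        from mammocad.fcm import FCMResult
        res = FCMResult(U=np.ones((2, 6)) / 2, V=np.zeros(2), labels=np.zeros(6, int),
                        J_trace=np.array([0.0]), E_trace=np.array([0.0]), iterations=1)
        with pytest.raises(DimensionError):
            hard_segmentation(res, (2, 4))


class TestContours:
    def test_filled_square_has_eight_boundary_pixels(self):
        labels = np.zeros((7, 7), int)
        labels[2:5, 2:5] = 1
        contours = extract_mass_contour(labels, 1)
        assert len(contours) == 1
        cont = contours[0]
        assert cont[0] == cont[-1]  # closed
        unique = set(cont)
        assert len(unique) == 8
        assert (3, 3) not in unique  # interior excluded

    def test_absent_class_gives_empty_list(self):
        assert extract_mass_contour(np.zeros((5, 5), int), 3) == []

    def test_two_disjoint_squares_give_two_contours(self):
        labels = np.zeros((12, 12), int)
        labels[1:4, 1:4] = 1
        labels[7:10, 7:10] = 1
        assert len(extract_mass_contour(labels, 1)) == 2

    def test_single_pixel_component(self):
        labels = np.zeros((5, 5), int)
        labels[2, 2] = 1
        (cont,) = extract_mass_contour(labels, 1)
        assert cont[0] == cont[-1] == (2, 2)
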