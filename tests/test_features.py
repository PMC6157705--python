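"""Derivative estimation, inflection detection and the sparse M2 assembly."""

import numpy as np
import pytest

from saxseg.features import (
    build_feature_matrix,
    extract_features,
    find_inflections,
    smooth_and_differentiate,
)
from saxseg.preprocess import CurveMatrix


def matrix(values, q):
    return CurveMatrix(values=np.atleast_2d(np.asarray(values, float)), q_centers=q)


class TestSmoothAndDifferentiate:
    def test_constant_row_has_zero_derivatives(self, log_uniform_grid):
        row = np.full(log_uniform_grid.size, 3.0)
        d1, d2 = smooth_and_differentiate(row, np.log(log_uniform_grid))
        assert np.allclose(d1, 0, atol=1e-10)
        assert np.allclose(d2, 0, atol=1e-10)

    def test_line_in_log_q_has_zero_second_derivative(self, log_uniform_grid):
        logq = np.log(log_uniform_grid)
        row = 2.0 + 5.0 * logq  # exact polynomial: reproduced by the fit
        d1, d2 = smooth_and_differentiate(row, logq)
        assert np.allclose(d1, 5.0, atol=1e-8)
        assert np.allclose(d2, 0, atol=1e-8)

    def test_gaussian_peak_derivative_zero_crossings(self, log_uniform_grid):
        mu, sigma = 2.0, 0.1
        row = np.exp(-((log_uniform_grid - mu) ** 2) / (2 * sigma**2))
        logq = np.log(log_uniform_grid)
        d1, d2 = smooth_and_differentiate(row, logq)
        bins = sorted(find_inflections(d1, d2, 0.05))
        targets = [mu - sigma, mu, mu + sigma]
        assert len(bins) == 3
        for b, t in zip(bins, targets):
            assert abs(b - np.argmin(np.abs(log_uniform_grid - t))) <= 1

    def test_window_larger_than_curve_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_and_differentiate(np.ones(5), np.log(np.geomspace(1, 2, 5)), window=7)


class TestFindInflections:
    def test_pure_power_law_yields_no_features(self, log_uniform_grid):
        row = 10.0 * log_uniform_grid**-2.5
        d1, d2 = smooth_and_differentiate(row, np.log(log_uniform_grid))
        assert find_inflections(d1, d2) == set()

    def test_two_disjoint_gaussians_match_analytic_sign_scan(self):
        # Each peak contributes {mu-sigma, mu, mu+sigma}; compositing adds
        # the inter-peak minimum, a genuine dI/dq = 0 point, so the
        # analytic brute-force scan of the derivatives gives 7 crossings.
        q = np.geomspace(1.0, 8.0, 600)
        row = np.exp(-((q - 2.0) ** 2) / (2 * 0.1**2)) + np.exp(
            -((q - 5.0) ** 2) / (2 * 0.25**2)
        )
        d1, d2 = smooth_and_differentiate(row, np.log(q))
        bins = find_inflections(d1, d2, 0.05)
        # brute-force oracle: scan analytic derivatives for sign changes
        def deriv(f, x, h=1e-6):
            return (f(x + h) - f(x - h)) / (2 * h)

        def intensity(x):
            return np.exp(-((x - 2.0) ** 2) / (2 * 0.1**2)) + np.exp(
                -((x - 5.0) ** 2) / (2 * 0.25**2)
            )

        # derivatives w.r.t. log q: dI/du = q dI/dq
        g1 = q * deriv(intensity, q)
        g2 = q * np.gradient(g1, np.log(q))
        expected = 0
        for g in (g1, g2):
            s = np.sign(g[np.abs(g) > 1e-8 * np.max(np.abs(g))])
            expected += int(np.sum(s[:-1] != s[1:]))
        assert len(bins) == expected == 7

    def test_shift_equivariance_by_one_bin(self):
        # a peak defined in bin-index space, translated by exactly one bin
        q = np.geomspace(1.0, 10.0, 200)
        idx = np.arange(200)

        def peak(center):
            return np.exp(-((idx - center) ** 2) / (2 * 8.0**2))

        d1a, d2a = smooth_and_differentiate(peak(100), np.log(q))
        d1b, d2b = smooth_and_differentiate(peak(101), np.log(q))
        a = find_inflections(d1a, d2a)
        b = find_inflections(d1b, d2b)
        assert sorted(x + 1 for x in a) == sorted(b)


class TestBuildFeatureMatrix:
    q = np.geomspace(1, 10, 20)

    def test_identical_rows_share_all_columns(self):
        mat = matrix(np.tile(np.arange(20.0), (3, 1)), self.q)
        fm = build_feature_matrix(mat, [{2, 5, 9}] * 3)
        assert fm.d == 3
        assert np.all(fm.values != 0)
        assert np.allclose(fm.feature_q, self.q[[2, 5, 9]])

    def test_disjoint_families_zero_filled(self):
        mat = matrix(np.ones((4, 20)), self.q)
        sets = [{1, 4, 7}, {1, 4, 7}, {10, 15}, {10, 15}]
        fm = build_feature_matrix(mat, sets)
        assert fm.d == 5
        assert np.all((fm.values == 0).sum(axis=1) >= 2)

    def test_featureless_row_retained_as_zeros(self):
        mat = matrix(np.ones((3, 20)), self.q)
        fm = build_feature_matrix(mat, [{3, 8}, set(), {8}])
        assert fm.values.shape == (3, 2)
        assert np.all(fm.values[1] == 0)

    def test_no_features_anywhere_aborts(self):
        mat = matrix(np.ones((2, 20)), self.q)
        with pytest.raises(ValueError, match="no features"):
            build_feature_matrix(mat, [set(), set()])

    def test_values_drawn_verbatim_from_source(self, rng):
        vals = rng.uniform(0.1, 5, size=(6, 20))
        mat = matrix(vals, self.q)
        sets = [set(rng.choice(20, size=3, replace=False).tolist()) for _ in range(6)]
        fm = build_feature_matrix(mat, sets)
        for i in range(6):
            for j, b in enumerate(fm.feature_bins):
                assert fm.values[i, j] in (0.0, vals[i, b])

    def test_extract_features_keeps_d_below_c(self, small_phantom):
        from saxseg.preprocess import log_resample, normalize_mean

        m1 = log_resample(
            normalize_mean(
                CurveMatrix(
                    values=small_phantom.noisy_curves,
                    q_centers=small_phantom.spec.q_grid,
                )
            ),
            10,
        )
        fm = extract_features(m1)
        assert 0 < fm.d < m1.c
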