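"""Proximal operators against independent fixed-point / scalar oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from rpcalign import (
    WeightScheme,
    l21_norm,
    l21_shrink,
    weighted_nuclear_norm,
    weighted_svt,
)
from rpcalign.prox import shrink_singular_values, soft_threshold, svt


def fixed_point_shrink(sigma_K: float, C: float, eps: float) -> float:
    """Independent oracle: iterate sigma <- max(sigma_K - C/(sigma+eps), 0)."""
    s = sigma_K
    for _ in range(1000):
        s_new = max(sigma_K - C / (s + eps), 0.0)
        if abs(s_new - s) < 1e-14:
            return s_new
        s = s_new
    return s


def scalar_l21_prox(u: np.ndarray, kappa: float) -> np.ndarray:
    """Numeric oracle: the minimiser of kappa*||e|| + 0.5*||u - e||^2 lies
    along u; minimise the 1-D restriction over the shrinkage amount."""
    nu = np.linalg.norm(u)
    if nu == 0:
        return np.zeros_like(u)
    res = minimize_scalar(
        lambda c: kappa * c + 0.5 * (nu - c) ** 2,
        bounds=(0.0, nu + kappa),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return res.x * u / nu


class TestWeightedSvt:
    def test_zero_matrix_maps_to_zero(self):
        out = weighted_svt(np.zeros((5, 4)), WeightScheme(b=1.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_vanishing_C_approaches_identity(self, rng):
        K = rng.normal(size=(6, 5))
        out = weighted_svt(K, WeightScheme(b=1.0, C=1e-18, epsilon=1e-16))
        np.testing.assert_allclose(out, K, atol=1e-8)

    def test_diag_example_against_fixed_point(self):
        scheme = WeightScheme(b=1.0, C=1.0, epsilon=1e-16)
        out = weighted_svt(np.diag([5.0, 1.0]), scheme)
        s = np.linalg.svd(out, compute_uv=False)
        eps = 1e-16
        expect = ((5 - eps) + np.sqrt((5 + eps) ** 2 - 4)) / 2
        np.testing.assert_allclose(s, [expect, 0.0], atol=1e-12)
        assert abs(fixed_point_shrink(5.0, 1.0, eps) - expect) < 1e-8
        assert fixed_point_shrink(1.0, 1.0, eps) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_equals_fixed_point_iteration(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.normal(size=rng.integers(3, 9, size=2))
        scheme = WeightScheme(b=float(rng.uniform(0.2, 2.0)))
        C = scheme.resolved_C(K.shape[1])
        sig = np.linalg.svd(K, compute_uv=False)
        closed = shrink_singular_values(sig, C, scheme.epsilon)
        oracle = [fixed_point_shrink(s, C, scheme.epsilon) for s in sig]
        np.testing.assert_allclose(closed, oracle, atol=1e-8)

    def test_shrinkage_bounds_and_rank(self, rng):
        K = rng.normal(size=(8, 6))
        scheme = WeightScheme(b=1.0)
        out = weighted_svt(K, scheme)
        s_in = np.linalg.svd(K, compute_uv=False)
        s_out = np.linalg.svd(out, compute_uv=False)
        assert np.all(s_out >= -1e-12)
        assert np.all(s_out <= s_in + 1e-12)
        assert np.linalg.matrix_rank(out) <= np.linalg.matrix_rank(K)

    def test_singular_vectors_preserved(self, rng):
        # distinct singular values: shrunk matrix shares singular subspaces
        U, _ = np.linalg.qr(rng.normal(size=(7, 3)))
        V, _ = np.linalg.qr(rng.normal(size=(4, 3)))
        K = (U * [9.0, 6.0, 4.0]) @ V.T
        scheme = WeightScheme(b=0.5, C=0.5)
        out = weighted_svt(K, scheme)
        s_hat = shrink_singular_values(np.array([9.0, 6.0, 4.0]), 0.5, 1e-16)
        np.testing.assert_allclose(out, (U * s_hat) @ V.T, atol=1e-10)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_svt(np.array([[np.inf, 0.0]]), WeightScheme())
        with pytest.raises(ValueError):
            WeightScheme(b=1.0, C=-1.0)


class TestL21Shrink:
    def test_zero_input(self):
        np.testing.assert_array_equal(l21_shrink(np.zeros((4, 3)), 1.0), 0.0)

    def test_pythagorean_column(self):
        out = l21_shrink(np.array([[3.0], [4.0]]), 1.0)
        np.testing.assert_allclose(out.ravel(), [2.4, 3.2])

    def test_below_threshold_column_zeroed(self):
        u = np.array([[0.3], [0.4]])  # norm 0.5 < kappa
        np.testing.assert_array_equal(l21_shrink(u, 1.0), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_prox_oracle(self, seed):
        rng = np.random.default_rng(seed)
        U = rng.normal(size=(6, 5))
        kappa = float(rng.uniform(0.3, 3.0))
        out = l21_shrink(U, kappa)
        for j in range(U.shape[1]):
            np.testing.assert_allclose(
                out[:, j], scalar_l21_prox(U[:, j], kappa), atol=1e-6
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.05, 5.0))
    def test_nonexpansive_columnwise(self, seed, kappa):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, 8)) * 3
        du = l21_shrink(u[:, None], kappa) - l21_shrink(v[:, None], kappa)
        assert np.linalg.norm(du) <= np.linalg.norm(u - v) + 1e-12

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            l21_shrink(np.ones((2, 2)), 0.0)


class TestNorms:
    def test_weighted_nuclear_zero_iff_zero(self, rng):
        scheme = WeightScheme(b=1.0)
        assert weighted_nuclear_norm(np.zeros((4, 4)), scheme) == 0.0
        assert weighted_nuclear_norm(rng.normal(size=(4, 4)), scheme) > 0.0

    def test_rank_one_single_term_formula(self):
        u = np.zeros((6, 1)); u[0] = 2.0
        v = np.ones((3, 1)) / np.sqrt(3)
        L = u @ v.T  # sigma1 = 2
        scheme = WeightScheme(b=1.5)
        got = weighted_nuclear_norm(L, scheme)
        expect = 1.5 * np.sqrt(3) * 2.0 / (2.0 + scheme.epsilon)
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_weighted_nuclear_direct_svd_oracle(self, rng):
        L = rng.normal(size=(5, 5))
        scheme = WeightScheme(b=0.7)
        s = np.linalg.svd(L, compute_uv=False)
        expect = float(np.sum(scheme.b * np.sqrt(5) / (s + scheme.epsilon) * s))
        assert abs(weighted_nuclear_norm(L, scheme) - expect) < 1e-10

    def test_literal_weight_mode(self, rng):
        L = rng.normal(size=(4, 6))
        scheme = WeightScheme(b=0.7, literal=True)
        s = np.linalg.svd(L, compute_uv=False)
        expect = float(np.sum(scheme.b / (6 * s + scheme.epsilon) * s))
        assert abs(weighted_nuclear_norm(L, scheme) - expect) < 1e-10

    def test_l21_norm_brute_force(self, rng):
        E = rng.normal(size=(7, 5))
        expect = sum(np.sqrt((E[:, j] ** 2).sum()) for j in range(5))
        assert abs(l21_norm(E) - expect) < 1e-12
        assert l21_norm(np.zeros((3, 3))) == 0.0
        assert l21_norm(np.array([[3.0, 0.0], [4.0, 0.0]])) == 5.0


class TestBaselineOps:
    def test_svt_soft_thresholds_spectrum(self, rng):
        K = rng.normal(size=(6, 4))
        s_in = np.linalg.svd(K, compute_uv=False)
        out = svt(K, 0.5)
        s_out = np.linalg.svd(out, compute_uv=False)
        np.testing.assert_allclose(s_out, np.maximum(s_in - 0.5, 0), atol=1e-10)

    def test_soft_threshold_elementwise(self):
        x = np.array([-2.0, -0.3, 0.0, 0.4, 1.5])
        np.testing.assert_allclose(
            soft_threshold(x, 0.5), [-1.5, 0.0, 0.0, 0.0, 1.0]
        )
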