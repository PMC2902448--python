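"""NIPALS extraction: SVD oracles, sparsity behavior, deflation bookkeeping."""

import itertools

import numpy as np
import pytest

import sspca
from sspca import CenteredMatrix, PenaltySpec, center_columns, fit, nipals_first_component, sparse_loading_step


class TestCenterColumns:
    def test_small_matrix_arithmetic(self):
        X = center_columns([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(X.values, [[-1, -1], [1, 1]])
        assert np.allclose(X.column_means, [2, 3])

    def test_constant_column_becomes_zero(self):
        X = center_columns([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        assert np.allclose(X.values[:, 0], 0)

    def test_already_centered_unchanged(self, rng):
        A = rng.standard_normal((10, 4))
        A -= A.mean(axis=0)
        X = center_columns(A)
        assert np.allclose(X.values, A)
        assert np.allclose(X.column_means, 0)
        assert np.allclose(X.values.mean(axis=0), 0, atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            center_columns([[1.0, np.nan], [2.0, 3.0]])

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            center_columns([[1.0, 2.0]])


class TestFirstComponent:
    def test_diagonal_matrix(self):
        A = CenteredMatrix(np.diag([3.0, 1.0]), np.zeros(2))
        v, z, d = nipals_first_component(A)
        assert np.allclose(np.abs(v), [1, 0], atol=1e-8)
        assert d == pytest.approx(3.0)

    def test_matches_dense_svd(self, rng):
        A = rng.standard_normal((20, 5))
        v, z, d = nipals_first_component(A)
        _, dd, Vt = np.linalg.svd(A)
        assert abs(v @ Vt[0]) > 1 - 1e-10
        assert d == pytest.approx(dd[0], rel=1e-10)
        assert np.allclose(z, A @ v)

    def test_rank_one_fixed_point(self, rng):
        u = rng.standard_normal(12)
        w = rng.standard_normal(6)
        w /= np.linalg.norm(w)
        v, _, _ = nipals_first_component(np.outer(u, w))
        assert abs(v @ w) > 1 - 1e-12


class TestSparseLoadingStep:
    def test_zero_penalty_is_ols(self, rng):
        A = rng.standard_normal((15, 4))
        z = rng.standard_normal(15)
        v = sparse_loading_step(A, z, PenaltySpec(family="none", lam=0.0))
        assert np.allclose(v, A.T @ z / (z @ z))

    def test_infinite_lasso_shrinks_to_zero(self, rng):
        A = rng.standard_normal((15, 4))
        z = rng.standard_normal(15)
        v = sparse_loading_step(A, z, PenaltySpec(family="lasso", lam=1e12))
        assert np.max(np.abs(v)) < 1e-6

    def test_recovers_support_vs_subset_search(self, rng):
        """HL step finds the same support as exhaustive best-subset search."""
        n, p, k_true = 30, 6, 2
        z = rng.standard_normal(n) * 3
        beta = np.zeros(p)
        beta[[1, 4]] = [1.0, -0.8]
        A = np.outer(z, beta) + 0.05 * rng.standard_normal((n, p))
        spec = PenaltySpec(family="hl", lam=5.0, theta=np.mean(beta**2), w=30.0)
        v = sparse_loading_step(A, z, spec)
        support = set(np.nonzero(np.abs(v) >= 5e-5)[0])
        # oracle: the size-2 OLS subset with smallest residual sum of squares
        ols = A.T @ z / (z @ z)
        best, best_rss = None, np.inf
        for comb in itertools.combinations(range(p), k_true):
            resid = A.copy()
            for j in comb:
                resid[:, j] -= ols[j] * z
            rss = np.sum(resid**2)
            if rss < best_rss:
                best, best_rss = set(comb), rss
        assert support == best == {1, 4}


class TestFit:
    @pytest.mark.parametrize("shape", [(80, 20), (50, 200)])
    def test_plain_fit_equals_dense_svd(self, rng, shape):
        X = center_columns(rng.standard_normal(shape))
        res = fit(X, k=3)
        _, d, Vt = np.linalg.svd(X.values)
        for i in range(3):
            assert abs(res.loadings[:, i] @ Vt[i]) > 1 - 1e-8
            assert res.singular_values[i] == pytest.approx(d[i], rel=1e-8)
        assert np.all(np.diff(res.singular_values) <= 1e-8)

    def test_deterministic_given_input(self, rng):
        X = center_columns(rng.standard_normal((30, 8)))
        a = fit(X, k=2)
        b = fit(X, k=2)
        assert np.array_equal(a.loadings, b.loadings)
        assert np.array_equal(a.scores, b.scores)

    def test_unit_norms_and_nonzero_counts(self, single_factor_80x20):
        X, truth, _ = single_factor_80x20
        spec = PenaltySpec(family="hl", lam=20.0, theta=0.04, w=30.0)
        res = fit(X, k=2, spec=spec)
        assert np.allclose(np.linalg.norm(res.loadings, axis=0), 1, atol=1e-8)
        for i in range(2):
            assert res.nonzero_counts[i] == np.sum(
                np.abs(res.loadings[:, i]) >= spec.zero_threshold
            )

    def test_deflation_removes_extracted_direction(self, rng):
        X = center_columns(rng.standard_normal((25, 6)))
        res = fit(X, k=1)
        deflated = X.values - np.outer(res.scores[:, 0], res.loadings[:, 0])
        assert np.linalg.norm(deflated @ res.loadings[:, 0]) < 1e-8

    def test_sparsity_monotone_in_lambda(self, single_factor_80x20):
        X, _, _ = single_factor_80x20
        counts = []
        for lam in [0.5, 2.0, 8.0, 32.0, 128.0]:
            spec = PenaltySpec(family="hl", lam=lam, theta=0.04, w=30.0)
            counts.append(fit(X, k=1, spec=spec).nonzero_counts[0])
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_hl_recovers_signal_support(self, single_factor_80x20):
        X, truth, _ = single_factor_80x20
        spec = PenaltySpec(family="hl", lam=20.0, theta=0.04, w=30.0)
        res = fit(X, k=1, spec=spec)
        support = set(np.nonzero(np.abs(res.loadings[:, 0]) >= 5e-5)[0])
        assert support <= {0, 1, 2, 3}

    def test_k_beyond_rank_rejected(self, rng):
        u = rng.standard_normal(10)
        w = rng.standard_normal(5)
        X = CenteredMatrix(np.outer(u, w) - np.outer(u, w).mean(0), np.zeros(5))
        with pytest.raises(ValueError):
            fit(X, k=3)

    def test_shrunken_fit_keeps_unit_norm_and_scores_from_data(self, single_factor_80x20):
        X, _, _ = single_factor_80x20
        res = fit(X, k=1, spec=PenaltySpec(family="hl", lam=20.0, theta=0.04, w=30.0),
                  use_condition_shrinkage=True, kappa_max=5.0)
        assert np.linalg.norm(res.loadings[:, 0]) == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(res.scores[:, 0], X.values @ res.loadings[:, 0])
        assert res.kappa_max == 5.0


class TestDeltaRobustness:
    def test_estimates_insensitive_to_delta(self, single_factor_80x20):
        """delta = 1e-8 and 1e-9 give nearly identical loadings."""
        X, _, _ = single_factor_80x20
        res = {}
        for delta in (1e-8, 1e-9):
            spec = PenaltySpec(family="hl", lam=20.0, theta=0.04, w=30.0, delta=delta)
            res[delta] = fit(X, k=1, spec=spec).loadings[:, 0]
        assert np.max(np.abs(res[1e-8] - res[1e-9])) < 1e-4
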