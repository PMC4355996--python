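"""Penalized positive-definite correlation estimation.

The iterative solver is checked against three independent oracles: direct
scalar arithmetic for the objective, the eigen-decomposition closed form at
lam = 0, and dense numeric searches over the free entries of 2x2 and 3x3
symmetric matrices.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from sqda.sparse_cov import (
    ZERO_TOL,
    barrier_eigen_solution,
    correlation_to_covariance,
    objective,
    sample_correlation,
    solve_penalized_correlation,
    stationarity_residual,
)

TAU = 1e-4


# ---------------------------------------------------------------- correlation


class TestSampleCorrelation:
    def test_identical_columns_correlate_perfectly(self, rng):
        x = rng.standard_normal(12)
        R = sample_correlation(np.column_stack([x, x]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_single_feature(self, rng):
        np.testing.assert_allclose(
            sample_correlation(rng.standard_normal((5, 1))), [[1.0]]
        )

    def test_matches_textbook_formula_on_small_matrix(self):
        # direct textbook formula cov/(sd*sd) on a 4x2 matrix
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [6.0, 4.0]])
        xc = X - X.mean(axis=0)
        expected = (xc[:, 0] * xc[:, 1]).sum() / 3.0
        expected /= np.sqrt((xc[:, 0] ** 2).sum() / 3.0 * (xc[:, 1] ** 2).sum() / 3.0)
        assert sample_correlation(X)[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_is_named(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="feature 1"):
            sample_correlation(X)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            sample_correlation(np.array([[1.0, 2.0]]))


# ----------------------------------------------------------------- objective


class TestObjective:
    def test_zero_at_identity_fixed_point(self):
        I = np.eye(4)
        assert objective(I, I, lam=3.0, tau=0.5) == pytest.approx(0.0)

    def test_scalar_arithmetic_1d(self):
        # 0.5*(2-1)^2 - 0.1*log 2 + 0
        val = objective(np.array([[2.0]]), np.array([[1.0]]), lam=5.0, tau=0.1)
        assert val == pytest.approx(0.5 - 0.1 * np.log(2.0), abs=1e-12)

    def test_l1_term_counts_offdiagonals_only(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        val = objective(R, np.eye(2), lam=1.0, tau=0.0)
        # Frobenius part 2*(0.5^2)/2 = 0.25; L1 part 2*|0.5| = 1.0
        assert val == pytest.approx(1.25, abs=1e-12)

    def test_rejects_non_positive_definite(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            objective(R, np.eye(2), lam=0.0, tau=0.1)


# ------------------------------------------------------------------- solver


def _random_symmetric(rng, d, eig_low, eig_high):
    """Random symmetric matrix with eigenvalues in the given range."""
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    w = rng.uniform(eig_low, eig_high, size=d)
    return (Q * w) @ Q.T


def dense_search_best(R_hat, lam, tau, rng, n_starts=6, maxfev=40000):
    """Best objective found by numeric search over free entries (oracle)."""
    d = R_hat.shape[0]
    iu = np.triu_indices(d)

    def unpack(v):
        R = np.zeros((d, d))
        R[iu] = v
        return R + R.T - np.diag(np.diag(R))

    def fun(v):
        R = unpack(v)
        w = np.linalg.eigvalsh(R)
        if w.min() <= 1e-10:
            return 1e8 * (1.0 + abs(w.min()))
        return objective(R, R_hat, lam, tau)

    starts = [np.eye(d)[iu]]
    proj = barrier_eigen_solution(R_hat, tau)
    starts.append(proj[iu])
    for _ in range(n_starts - 2):
        starts.append(proj[iu] + 0.1 * rng.standard_normal(len(iu[0])))
    best = np.inf
    for s in starts:
        res = minimize(
            fun, s, method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxfev": maxfev},
        )
        best = min(best, res.fun)
    return best


class TestSolver:
    def test_eigen_closed_form_at_lam_zero(self, rng):
        for d in (2, 5, 12, 20):
            # eigenvalues above -2*sqrt(tau), where the closed form applies
            R_hat = _random_symmetric(rng, d, -0.015, 2.0)
            sol = solve_penalized_correlation(R_hat, lam=0.0, tau=TAU, tol=1e-10)
            assert sol.converged
            ref = barrier_eigen_solution(R_hat, TAU)
            np.testing.assert_allclose(sol.R_tilde, ref, atol=1e-8)

    def test_identity_target_stays_diagonal(self):
        for lam in (0.0, 0.2, 1.0):
            sol = solve_penalized_correlation(np.eye(4), lam=lam, tau=TAU)
            off = ~np.eye(4, dtype=bool)
            assert np.all(sol.R_tilde[off] == 0.0)
            diag_ref = (1.0 + np.sqrt(1.0 + 4.0 * TAU)) / 2.0
            np.testing.assert_allclose(np.diag(sol.R_tilde), diag_ref, atol=1e-8)

    def test_one_by_one_closed_form(self):
        sol = solve_penalized_correlation(np.array([[1.0]]), lam=0.3, tau=TAU)
        assert sol.R_tilde[0, 0] == pytest.approx((1 + np.sqrt(1 + 4 * TAU)) / 2)

    @pytest.mark.parametrize("lam", [0.1, 0.3, 0.7])
    def test_two_by_two_matches_grid_search(self, lam):
        """Exchangeable 2x2 case against an exhaustive two-parameter grid."""
        R_hat = np.array([[1.0, 0.6], [0.6, 1.0]])
        sol = solve_penalized_correlation(R_hat, lam=lam, tau=TAU)

        # by symmetry the solution is [[a, c], [c, a]]; vectorized grid oracle
        def best_on(a_lo, a_hi, c_lo, c_hi, n):
            a, c = np.meshgrid(
                np.linspace(a_lo, a_hi, n), np.linspace(c_lo, c_hi, n), indexing="ij"
            )
            det = (a - c) * (a + c)
            with np.errstate(divide="ignore", invalid="ignore"):
                val = np.where(
                    (a > np.abs(c)) & (det > 0),
                    (a - 1.0) ** 2 + (c - 0.6) ** 2 - TAU * np.log(np.abs(det))
                    + lam * 2.0 * np.abs(c),
                    np.inf,
                )
            i, j = np.unravel_index(np.argmin(val), val.shape)
            return a[i, j], c[i, j]

        a, c = best_on(0.5, 1.5, -0.1, 0.7, 401)
        for _ in range(3):  # refine around the coarse optimum
            da = 2.0 / 400
            a, c = best_on(a - da, a + da, c - da, c + da, 401)
            da /= 200
        assert sol.R_tilde[0, 0] == pytest.approx(a, abs=1e-4)
        assert sol.R_tilde[0, 1] == pytest.approx(c, abs=1e-4)
        if lam == 0.7:
            assert sol.R_tilde[0, 1] == 0.0  # soft threshold kills a 0.6 correlation

    def test_objective_not_beaten_by_dense_search_3x3(self, rng):
        for _ in range(3):
            R_hat = _random_symmetric(rng, 3, 0.05, 2.0)
            for lam in (0.05, 0.3):
                sol = solve_penalized_correlation(R_hat, lam=lam, tau=TAU)
                oracle = dense_search_best(R_hat, lam, TAU, rng)
                assert sol.objective <= oracle + 1e-6

    def test_sparsity_monotone_in_lambda(self, rng):
        X = rng.standard_normal((15, 10)) @ _random_symmetric(rng, 10, 0.2, 2.0)
        R_hat = sample_correlation(X)
        zeros = [
            solve_penalized_correlation(R_hat, lam, tau=TAU).n_zero_offdiag
            for lam in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a <= b for a, b in zip(zeros, zeros[1:]))
        assert zeros[-1] == 10 * 9  # lam -> large: fully diagonal

    def test_solution_invariants(self, rng):
        X = rng.standard_normal((20, 8))
        R_hat = sample_correlation(X)
        sol = solve_penalized_correlation(R_hat, lam=0.15, tau=TAU)
        assert np.abs(sol.R_tilde - sol.R_tilde.T).max() < 1e-10
        assert np.linalg.eigvalsh(sol.R_tilde).min() > 0
        off = ~np.eye(8, dtype=bool)
        small = np.abs(sol.R_tilde[off]) < ZERO_TOL
        assert np.all(sol.R_tilde[off][small] == 0.0)
        assert stationarity_residual(sol.R_tilde, R_hat, 0.15, TAU) < 1e-6

    def test_input_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            solve_penalized_correlation(np.array([[1.0, 0.2], [0.5, 1.0]]), 0.1)
        with pytest.raises(ValueError, match="non-negative"):
            solve_penalized_correlation(np.eye(2), -0.1)
        with pytest.raises(ValueError, match="tau"):
            solve_penalized_correlation(np.eye(2), 0.1, tau=0.0)


# ------------------------------------------------------------------ rescale


class TestCorrelationToCovariance:
    def test_identity_rescales_to_diagonal(self):
        sol = solve_penalized_correlation(np.eye(2), lam=0.0, tau=1e-9)
        est = correlation_to_covariance(sol, np.array([4.0, 9.0]))
        np.testing.assert_allclose(est.sigma, np.diag([4.0, 9.0]), atol=1e-4)

    def test_offdiagonal_scaling(self):
        sol = solve_penalized_correlation(np.eye(2), lam=0.0, tau=TAU)
        sol.R_tilde = np.array([[1.0, 0.5], [0.5, 1.0]])
        est = correlation_to_covariance(sol, np.array([1.0, 4.0]))
        assert est.sigma[0, 1] == pytest.approx(1.0)

    def test_zero_pattern_and_positive_definiteness_preserved(self, rng):
        X = rng.standard_normal((12, 6))
        sol = solve_penalized_correlation(sample_correlation(X), lam=0.3, tau=TAU)
        var = rng.uniform(0.5, 5.0, size=6)
        est = correlation_to_covariance(sol, var)
        assert np.array_equal(est.sigma == 0, sol.R_tilde == 0)
        assert np.linalg.eigvalsh(est.sigma).min() > 0

    def test_rejects_non_positive_variance(self):
        sol = solve_penalized_correlation(np.eye(2), lam=0.0, tau=TAU)
        with pytest.raises(ValueError, match="feature 1"):
            correlation_to_covariance(sol, np.array([1.0, 0.0]))
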