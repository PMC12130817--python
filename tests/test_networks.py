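"""Losses, masking, and cross-class reconstruction identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contextnets import (
    correlation_loss,
    markov_loss,
    mask_diagonal,
    neighborhood_loss,
    partial_correlation,
    reconstruct_correlation,
    reconstruct_precision,
)
from contextnets.networks import NetworkClass, loss_and_grad

from conftest import standardized


def _standardized_pair(r, n=4000, seed=0):
    """Bivariate standardized sample with (empirical) correlation ~ r."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x1 = z[:, 0]
    x2 = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]
    return standardized(np.column_stack([x1, x2]))


class TestMaskDiagonal:
    def test_zeroes_diagonal_keeps_offdiagonal(self):
        out = mask_diagonal([[5.0, 2.0], [3.0, 7.0]])
        assert np.array_equal(out, [[0.0, 2.0], [3.0, 0.0]])

    @pytest.mark.parametrize("mat", [np.eye(4), np.zeros((3, 3))])
    def test_identity_and_zero_map_to_zero(self, mat):
        assert np.array_equal(mask_diagonal(mat), np.zeros_like(mat))

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            mask_diagonal(np.ones((2, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_idempotent_and_preserves_offdiagonal(self, p, seed):
        m = np.random.default_rng(seed).normal(size=(p, p))
        out = mask_diagonal(m)
        assert np.all(np.diagonal(out) == 0.0)
        assert np.array_equal(out, mask_diagonal(out))
        off = ~np.eye(p, dtype=bool)
        assert np.array_equal(out[off], m[off])


class TestNeighborhoodLoss:
    def test_perfect_mutual_prediction(self):
        X = np.array([[1.0, 1.0], [-1.0, -1.0]])
        assert neighborhood_loss(np.array([[0.0, 1.0], [1.0, 0.0]]), X) == 0.0

    def test_zero_network_gives_mean_square(self):
        X = np.array([[1.0, 1.0], [-1.0, -1.0]])
        assert neighborhood_loss(np.zeros((2, 2)), X) == pytest.approx(1.0)

    def test_minimum_matches_univariate_ols(self):
        # standardized bivariate data: optimal cross-coefficients are the
        # empirical correlation r, and the minimal loss is 1 - r^2
        X = _standardized_pair(0.5)
        r = float(np.mean(X[:, 0] * X[:, 1]))
        theta = np.array([[0.0, r], [r, 0.0]])
        assert neighborhood_loss(theta, X) == pytest.approx(1 - r**2, abs=1e-10)
        # any perturbation does worse
        for eps in (0.01, -0.01):
            worse = np.array([[0.0, r + eps], [r, 0.0]])
            assert neighborhood_loss(worse, X) > neighborhood_loss(theta, X)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            neighborhood_loss(np.zeros((3, 3)), np.zeros((4, 2)))


class TestMarkovLoss:
    def test_symmetrized_perfect_prediction(self):
        X = np.array([[1.0, 1.0], [-1.0, -1.0]])
        gamma = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert markov_loss(gamma, X) == pytest.approx(0.0)

    def test_zero_gamma_gives_mean_square(self):
        X = np.array([[1.0, 1.0], [-1.0, -1.0]])
        assert markov_loss(np.zeros((2, 2)), X) == pytest.approx(1.0)

    def test_optimal_symmetric_coefficient_equals_r(self):
        # minimize 2(1 - 2tr + t^2) over the symmetric off-diagonal t: t* = r
        X = _standardized_pair(0.5, seed=3)
        r = float(np.mean(X[:, 0] * X[:, 1]))
        ts = np.linspace(r - 0.2, r + 0.2, 81)
        losses = [
            markov_loss(np.array([[0.0, t / 2], [t / 2, 0.0]]), X) for t in ts
        ]
        assert ts[int(np.argmin(losses))] == pytest.approx(r, abs=0.01)


class TestCorrelationLoss:
    def test_identity_theta_diagonal_contributes_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        loss_id = correlation_loss(np.eye(3), X)
        # total = mean over all p^2 pairs; off-diagonal residual is X_j itself
        off_sum = sum(
            np.sum(X[:, j] ** 2) for i in range(3) for j in range(3) if i != j
        )
        assert loss_id == pytest.approx(off_sum / (50 * 9))

    def test_minimizer_is_pearson_r_on_standardized_data(self):
        X = _standardized_pair(0.5, seed=5)
        r = float(np.mean(X[:, 0] * X[:, 1]))
        best = np.array([[1.0, r], [r, 1.0]])
        assert correlation_loss(best, X) <= correlation_loss(np.eye(2), X)
        grad_free = loss_and_grad(best[None].repeat(len(X), 0), X, "correlation")[1]
        assert np.abs(grad_free.sum(axis=0)).max() < 1e-8

    def test_zero_gene_column_optimal_coefficient_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.standard_normal(100), np.zeros(100)])
        # coefficient out of the zero gene cannot reduce loss below theta=0
        theta0 = np.array([[1.0, 0.0], [0.0, 0.0]])
        theta1 = np.array([[1.0, 0.0], [0.5, 0.0]])
        assert correlation_loss(theta0, X) <= correlation_loss(theta1, X)


class TestReconstruction:
    def test_precision_from_gamma(self):
        gamma = np.array([[0.0, 0.2], [0.3, 0.0]])
        expect = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert np.allclose(reconstruct_precision(gamma), expect)

    def test_zero_gamma_gives_identity(self):
        assert np.array_equal(reconstruct_precision(np.zeros((3, 3))), np.eye(3))

    def test_fitted_bivariate_roundtrip_matches_inverse_correlation(self):
        # for 2 genes the partial correlation equals the marginal correlation
        X = _standardized_pair(0.5, seed=9)
        r = float(np.mean(X[:, 0] * X[:, 1]))
        from contextnets.baselines import fit_single_network

        gamma = fit_single_network(X, NetworkClass.MARKOV)
        omega = reconstruct_precision(gamma)
        # oracle: invert the empirical correlation matrix, rescale diag to 1
        S = np.array([[1.0, r], [r, 1.0]])
        oracle = np.linalg.inv(S)
        oracle = oracle / oracle[0, 0]
        assert omega[0, 1] == pytest.approx(oracle[0, 1], abs=1e-6)
        assert omega[0, 1] == pytest.approx(-r, abs=1e-6)

    def test_markov_precision_exactly_symmetric(self):
        rng = np.random.default_rng(4)
        gamma = mask_diagonal(rng.normal(size=(20, 6, 6)))
        omega = reconstruct_precision(gamma)
        assert np.array_equal(omega, np.swapaxes(omega, -1, -2))

    def test_squared_correlation_products(self):
        theta = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert reconstruct_correlation(theta)[0, 1] == pytest.approx(0.25)
        theta2 = np.array([[1.0, 0.8], [0.2, 1.0]])
        assert reconstruct_correlation(theta2)[0, 1] == pytest.approx(0.16)

    def test_fitted_correlation_equals_squared_pearson(self):
        X = _standardized_pair(0.5, seed=11)
        from contextnets.baselines import fit_single_network

        theta = fit_single_network(X, NetworkClass.CORRELATION)
        r = float(np.corrcoef(X.T)[0, 1])
        rho2 = reconstruct_correlation(theta)
        assert theta[0, 1] * theta[1, 0] >= 0
        assert rho2[0, 1] == pytest.approx(r**2, abs=1e-4)

    def test_out_of_range_products_clipped_with_warning(self):
        theta = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.warns(UserWarning, match="clipped"):
            out = reconstruct_correlation(theta)
        assert out[0, 1] == 1.0


class TestPartialCorrelation:
    def test_closed_form_2x2(self):
        omega = np.array([[2.0, -1.0], [-1.0, 2.0]])
        rho = partial_correlation(omega)
        assert rho[0, 1] == pytest.approx(0.5)
        # cross-check against the marginal correlation of Sigma = Omega^-1
        sigma = np.linalg.inv(omega)
        marg = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert rho[0, 1] == pytest.approx(marg)

    def test_diagonal_precision_gives_zero_offdiagonal(self):
        rho = partial_correlation(np.diag([1.0, 2.0, 3.0]))
        assert np.array_equal(rho, np.eye(3))

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(4, 4))
        omega = A @ A.T + 4 * np.eye(4)
        assert np.allclose(partial_correlation(omega), partial_correlation(7.3 * omega))

    def test_rejects_nonpositive_diagonal(self):
        with pytest.raises(ValueError):
            partial_correlation(np.array([[0.0, 1.0], [1.0, 1.0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_conditional_covariance_oracle(self, seed):
        """rho_ij from the precision equals the correlation of X_i, X_j given the rest.

        Independent oracle: condition the covariance Sigma = Omega^-1 on all
        other coordinates explicitly and correlate the 2x2 conditional block.
        """
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 6))
        A = rng.normal(size=(p, p))
        omega = A @ A.T + p * np.eye(p)
        rho = partial_correlation(omega)
        sigma = np.linalg.inv(omega)
        for i in range(p):
            for j in range(i + 1, p):
                rest = [k for k in range(p) if k not in (i, j)]
                S11 = sigma[np.ix_([i, j], [i, j])]
                S12 = sigma[np.ix_([i, j], rest)]
                S22 = sigma[np.ix_(rest, rest)]
                cond = S11 - S12 @ np.linalg.inv(S22) @ S12.T
                expect = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
                assert rho[i, j] == pytest.approx(expect, abs=1e-10)


class TestLossGradients:
    @pytest.mark.parametrize("network_class", ["neighborhood", "markov", "correlation"])
    def test_analytic_gradient_matches_finite_differences(self, network_class):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 3))
        theta = rng.normal(size=(6, 3, 3))
        lam = 0.0 if network_class == "correlation" else 0.05
        loss, grad = loss_and_grad(theta, X, network_class, lam)
        eps = 1e-6
        for _ in range(10):
            n, i, j = rng.integers(6), rng.integers(3), rng.integers(3)
            tp = theta.copy()
            tp[n, i, j] += eps
            lp, _ = loss_and_grad(tp, X, network_class, lam)
            fd = (lp - loss) / eps
            assert grad[n, i, j] == pytest.approx(fd, abs=1e-4)
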