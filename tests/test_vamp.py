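"""Covariance estimators, regularised inverses, VAMP scores and gradients."""

import numpy as np
import pytest

from vampnet import (
    CovarianceSet,
    LaggedDataset,
    estimate_covariances,
    regularized_inverse_sqrt,
    validation_score,
    vamp1_gradients,
    vamp2_gradients,
    vamp_score,
)
from vampnet.vamp import _covariances_from_matrices

from conftest import LAMBDA2, P_TWO_STATE, PI_TWO_STATE, chain_onehot


def analytic_meanfree_covariances(P, pi, features):
    """Exact mean-free covariances of feature-mapped states of a stationary
    chain: C00 = F^T (diag(pi) - pi pi^T) F, C01 = F^T (diag(pi) P - pi pi^T) F."""
    F = np.atleast_2d(features)
    M0 = np.diag(pi) - np.outer(pi, pi)
    M1 = np.diag(pi) @ P - np.outer(pi, pi)
    return CovarianceSet(
        C00=F.T @ M0 @ F,
        C01=F.T @ M1 @ F,
        C11=F.T @ M0 @ F,
        mean0=F.T @ pi,
        mean1=F.T @ pi,
        mean_free=True,
        T=10**9,
    )


class TestEstimateCovariances:
    def test_constant_feature_centers_to_zero(self):
        ds = LaggedDataset.from_trajectory(np.arange(10.0), lag=1)
        cov = estimate_covariances(ds, transform=lambda x: np.ones_like(x), mean_free=True)
        assert np.allclose(cov.C00, 0) and np.allclose(cov.C01, 0) and np.allclose(cov.C11, 0)

    def test_lag_zero_self_pairs_are_identical(self):
        rng = np.random.default_rng(0)
        ds = LaggedDataset.from_trajectory(rng.standard_normal((50, 3)), lag=0)
        cov = estimate_covariances(ds, mean_free=True)
        assert np.allclose(cov.C01, cov.C00)
        assert np.allclose(cov.C11, cov.C00)

    def test_matches_hand_summation(self):
        # 4 frames, 2 features, lag 1 -> T = 3 pairs, divisor T - 1 = 2
        frames = np.array([[1.0, 0.0], [2.0, 1.0], [0.0, 3.0], [1.0, 1.0]])
        ds = LaggedDataset.from_trajectory(frames, lag=1)
        cov = estimate_covariances(ds, mean_free=True)
        X, Y = frames[:3], frames[1:]
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        assert np.allclose(cov.C00, (Xc.T @ Xc) / 2)
        assert np.allclose(cov.C01, (Xc.T @ Yc) / 2)
        assert np.allclose(cov.C11, (Yc.T @ Yc) / 2)
        assert cov.T == 3

    def test_raw_divisor_is_T(self):
        frames = np.array([[1.0], [3.0], [2.0]])
        ds = LaggedDataset.from_trajectory(frames, lag=1)
        cov = estimate_covariances(ds, mean_free=False)
        assert np.allclose(cov.C00, (1 + 9) / 2)

    def test_empty_and_nonfinite_inputs_error(self):
        with pytest.raises(ValueError, match="no pairs"):
            LaggedDataset.from_trajectory(np.array([1.0]), lag=1)
        ds = LaggedDataset.from_trajectory(np.array([1.0, np.nan, 2.0]), lag=1)
        with pytest.raises(ValueError, match="invalid input"):
            estimate_covariances(ds)

    def test_symmetry_and_psd_invariants(self):
        rng = np.random.default_rng(1)
        ds = LaggedDataset.from_trajectory(rng.standard_normal((200, 4)), lag=2)
        cov = estimate_covariances(ds, mean_free=True)
        for M in (cov.C00, cov.C11):
            assert np.allclose(M, M.T, rtol=1e-10)
            assert np.linalg.eigvalsh(M).min() >= -1e-10 * np.trace(M)


class TestRegularizedInverseSqrt:
    def test_identity(self):
        assert np.allclose(regularized_inverse_sqrt(np.eye(3)), np.eye(3))

    def test_diagonal_closed_form(self):
        assert np.allclose(regularized_inverse_sqrt(np.diag([4.0, 1.0])), np.diag([0.5, 1.0]))

    def test_rank_deficient_gives_projector(self):
        rng = np.random.default_rng(2)
        B = rng.standard_normal((4, 2))
        M = B @ B.T  # rank 2
        R = regularized_inverse_sqrt(M, epsilon=1e-10)
        evals, evecs = np.linalg.eigh(M)
        keep = evals > 1e-10 * evals.max()
        proj = evecs[:, keep] @ evecs[:, keep].T
        assert np.allclose(R @ M @ R, proj, atol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError, match="rank zero"):
            regularized_inverse_sqrt(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="not PSD"):
            regularized_inverse_sqrt(np.diag([1.0, -0.5]))


class TestVampScore:
    def test_constant_feature_scores_one_with_constant(self):
        cov = CovarianceSet(
            np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
            np.ones(1), np.ones(1), True, 100,
        )
        assert vamp_score(cov, 2, "full", include_constant=True).value == pytest.approx(1.0)

    def test_two_state_analytic_score(self):
        # single mean-free indicator feature of the reversible 2-state chain
        cov = analytic_meanfree_covariances(P_TWO_STATE, PI_TWO_STATE, np.array([[1.0], [0.0]]))
        with pytest.warns(UserWarning, match="treated as zero"):
            rep = vamp_score(cov, 2, k=2, include_constant=True)
        assert rep.value == pytest.approx(1.0 + LAMBDA2**2, abs=1e-12)
        assert rep.singular_values[0] == pytest.approx(LAMBDA2)

    def test_lag_zero_scores_k(self):
        rng = np.random.default_rng(3)
        ds = LaggedDataset.from_trajectory(rng.standard_normal((100, 3)), lag=0)
        cov = estimate_covariances(ds, mean_free=True)
        rep = vamp_score(cov, 2, k=2, include_constant=True)
        assert rep.value == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(rep.singular_values, 1.0)

    def test_order_one_sums_singular_values(self):
        cov = analytic_meanfree_covariances(P_TWO_STATE, PI_TWO_STATE, np.eye(2))
        rep = vamp_score(cov, 1, "full", include_constant=True)
        assert rep.value == pytest.approx(1.0 + LAMBDA2, abs=1e-10)

    def test_normalized_mode_divides_by_dimension(self):
        cov = analytic_meanfree_covariances(P_TWO_STATE, PI_TWO_STATE, np.eye(2))
        full = vamp_score(cov, 2, "full").value
        norm = vamp_score(cov, 2, "full", normalized=True).value
        assert norm == pytest.approx(full / 2)

    def test_invariance_under_invertible_linear_maps(self):
        rng = np.random.default_rng(4)
        frames = rng.standard_normal((500, 3))
        ds = LaggedDataset.from_trajectory(frames, lag=1)
        base = vamp_score(estimate_covariances(ds), 2, "full").value
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        mapped = vamp_score(
            estimate_covariances(ds, transform=lambda x: x @ A), 2, "full"
        ).value
        assert mapped == pytest.approx(base, abs=1e-8)

    def test_role_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        ds = LaggedDataset.from_trajectory(rng.standard_normal((300, 2)), lag=1)
        cov = estimate_covariances(ds)
        swapped = CovarianceSet(
            cov.C11, cov.C01.T, cov.C00, cov.mean1, cov.mean0, True, cov.T
        )
        assert vamp_score(swapped, 2, "full").value == pytest.approx(
            vamp_score(cov, 2, "full").value, abs=1e-10
        )

    def test_variational_bound_on_known_chains(self):
        # random reversible 3-state chain: any feature map scores at most
        # 1 + sum of squared non-unit eigenvalues; indicators reach the bound
        rng = np.random.default_rng(6)
        C = rng.random((3, 3)) + np.eye(3)
        C = C + C.T
        P = C / C.sum(axis=1, keepdims=True)
        pi = C.sum(axis=1) / C.sum()
        lams = np.sort(np.abs(np.linalg.eigvals(P)))[::-1]
        bound = 1.0 + np.sum(lams[1:] ** 2)
        for _ in range(10):
            F = rng.standard_normal((3, 2))
            score = vamp_score(
                analytic_meanfree_covariances(P, pi, F), 2, "full", include_constant=True
            ).value
            assert score <= bound + 1e-10
        exact = vamp_score(
            analytic_meanfree_covariances(P, pi, np.eye(3)), 2, "full", include_constant=True
        ).value
        assert exact == pytest.approx(bound, abs=1e-10)


def _score_of_matrices(X, Y, order=2):
    cov = _covariances_from_matrices(X.T, Y.T, mean_free=True)
    return vamp_score(cov, order, "full").value


class TestGradients:
    @pytest.mark.parametrize("grad_fn,order", [(vamp2_gradients, 2), (vamp1_gradients, 1)])
    def test_matches_finite_differences(self, grad_fn, order):
        rng = np.random.default_rng(7)
        for trial in range(20):
            X = rng.standard_normal((3, 50))
            Y = rng.standard_normal((3, 50))
            gX, gY = grad_fn(X, Y)
            eps = 1e-6
            for arr, grad in ((X, gX), (Y, gY)):
                i = int(rng.integers(3))
                j = int(rng.integers(50))
                plus, minus = arr.copy(), arr.copy()
                plus[i, j] += eps
                minus[i, j] -= eps
                if arr is X:
                    fd = (_score_of_matrices(plus, Y, order) - _score_of_matrices(minus, Y, order)) / (2 * eps)
                else:
                    fd = (_score_of_matrices(X, plus, order) - _score_of_matrices(X, minus, order)) / (2 * eps)
                assert grad[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_row_sums_vanish(self):
        # mean-free construction makes the score shift-invariant
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 60))
        Y = rng.standard_normal((4, 60))
        for g in vamp2_gradients(X, Y) + vamp1_gradients(X, Y):
            assert np.abs(g.sum(axis=1)).max() < 1e-10

    def test_scalar_closed_form(self):
        # m = 1: d/dx of sigma^2 = c01^2 / (c00 c11) expanded by hand
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        gX, _ = vamp2_gradients(x[None, :], y[None, :])
        T = 30
        xc, yc = x - x.mean(), y - y.mean()
        c00 = xc @ xc / (T - 1)
        c01 = xc @ yc / (T - 1)
        c11 = yc @ yc / (T - 1)
        expected = (2 / (T - 1)) * (c01 / (c00 * c11)) * (yc - (c01 / c00) * xc)
        assert np.allclose(gX[0], expected, rtol=1e-10)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            vamp2_gradients(np.ones((2, 1)), np.ones((2, 1)))


class TestValidationScore:
    def test_heldout_equals_training_set_score(self, two_state_dataset):
        rep = validation_score(None, two_state_dataset, k="full")
        cov = estimate_covariances(two_state_dataset, mean_free=True)
        assert rep.value == pytest.approx(
            vamp_score(cov, 2, "full", include_constant=True).value
        )

    def test_fresh_sample_near_analytic_maximum(self):
        fresh = LaggedDataset.from_trajectory(chain_onehot(P_TWO_STATE, 50_000, seed=42), lag=1)
        rep = validation_score(None, fresh, k="full")
        # bootstrap standard error of the score over transition pairs
        rng = np.random.default_rng(0)
        x, y = fresh.pairs()
        reps = []
        for _ in range(50):
            idx = rng.integers(0, len(x), len(x))
            reps.append(
                vamp_score(
                    _covariances_from_matrices(x[idx], y[idx], True),
                    2, "full", include_constant=True,
                ).value
            )
        se = np.std(reps)
        assert abs(rep.value - 1.49) < 3 * se

    def test_single_pair_errors(self):
        ds = LaggedDataset.from_trajectory(np.array([0.0, 1.0]), lag=1)
        with pytest.raises(ValueError, match="no validation data"):
            validation_score(None, ds, k=1)
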