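import numpy as np
import pytest
from scipy.spatial import procrustes

import bicca
from bicca.core import (
    compute_scale_factors,
    cross_product,
    evaluate_objective,
    fit_cca_pair,
    monitored_objective,
    standardize_rows,
    update_fusion_matrix,
)
from bicca.types import ValidationError


def _std(rng, shape):
    A = rng.normal(size=shape)
    return (A - A.mean(1, keepdims=True)) / A.std(1, keepdims=True)


# ---------------------------------------------------------------- oracles


def oracle_svd_via_eigh(Sigma, E):
    """Independent dense eigen-decomposition of Sigma Sigma'."""
    lam, W = np.linalg.eigh(Sigma @ Sigma.T)
    order = np.argsort(lam)[::-1][:E]
    W = W[:, order]
    s = np.sqrt(np.maximum(lam[order], 0))
    V = Sigma.T @ W / s
    return W, V, s


def oracle_update_z(X, Y, U, S, T, V, Z0, alpha, lam, n_l, n_r):
    """Explicit triple-loop evaluation of the fusion update + norm."""
    M, L = Z0.shape
    Z = np.zeros((M, L))
    for i in range(M):
        for j in range(L):
            left = sum(X[i, k] * U[k, e] * S[j, e]
                       for k in range(X.shape[1]) for e in range(U.shape[1]))
            right = sum(T[i, e] * V[n, e] * Y[n, j]
                        for n in range(Y.shape[0]) for e in range(T.shape[1]))
            Z[i, j] = (1 - alpha) * ((1 - lam) / n_l * left + lam / n_r * right) \
                + alpha * Z0[i, j]
    return Z / np.sqrt((Z ** 2).sum())


def oracle_objective(X, Y, Z, Z0, U, S, T, V, alpha, lam, n_l, n_r):
    """Explicit-loop trace evaluation of the penalized objective."""
    A = (X @ U).T @ Z @ S
    B = (Z.T @ T).T @ (Y.T @ V)
    tr = sum(A[e, e] for e in range(A.shape[0]))
    tr2 = sum(B[e, e] for e in range(B.shape[0]))
    pen = ((Z - Z0) ** 2).sum()
    return (1 - alpha) * ((1 - lam) / n_l * tr + lam / n_r * tr2) - alpha * pen


# ---------------------------------------------------------------- fit_cca_pair


class TestFitCcaPair:
    def test_diagonal_cross_product(self):
        # A'B = diag(3, 1) by construction
        A = np.array([[3.0, 0.0], [0.0, 1.0]])
        B = np.eye(2)
        left, right, corr, sv = fit_cca_pair(A, B, 2)
        np.testing.assert_allclose(np.abs(left), np.eye(2), atol=1e-12)
        np.testing.assert_allclose(np.abs(right), np.eye(2), atol=1e-12)
        np.testing.assert_allclose(sv, [3.0, 1.0])
        np.testing.assert_allclose(corr, [3.0, 1.0])  # M=2 -> 1/(M-1)=1

    def test_self_pair_gives_equal_sides(self):
        rng = np.random.default_rng(0)
        A = _std(rng, (9, 6))
        left, right, corr, _ = fit_cca_pair(A, A, 2)
        np.testing.assert_allclose(left, right, atol=1e-8)
        assert np.all(np.diff(corr) <= 1e-12)  # non-increasing

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_dense_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, B = _std(rng, (8, 6)), _std(rng, (8, 5))
        left, right, corr, sv = fit_cca_pair(A, B, 3)
        Wo, Vo, so = oracle_svd_via_eigh(A.T @ B, 3)
        np.testing.assert_allclose(sv, so, atol=1e-8)
        for j in range(3):
            sign = np.sign(left[np.argmax(np.abs(left[:, j])), j]
                           * Wo[np.argmax(np.abs(left[:, j])), j])
            np.testing.assert_allclose(left[:, j], sign * Wo[:, j], atol=1e-8)
            np.testing.assert_allclose(right[:, j], sign * Vo[:, j], atol=1e-8)
        np.testing.assert_allclose(corr, sv / (A.shape[0] - 1))

    def test_rank_deficient_truncates_with_warning(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(7, 2)) @ rng.normal(size=(2, 5))
        B = rng.normal(size=(7, 4))
        with pytest.warns(UserWarning, match="rank"):
            left, right, corr, _ = fit_cca_pair(A, B, 4)
        assert left.shape[1] == 2

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(5)
        A, B = _std(rng, (10, 7)), _std(rng, (10, 6))
        l1, r1, *_ = fit_cca_pair(A, B, 3)
        l2, r2, *_ = fit_cca_pair(A, B, 3)
        np.testing.assert_array_equal(l1, l2)
        for j in range(3):
            assert l1[np.argmax(np.abs(l1[:, j])), j] > 0


class TestCrossProduct:
    @pytest.mark.parametrize("block_size", [1, 7, 1000])
    def test_blocked_matches_unblocked(self, block_size):
        rng = np.random.default_rng(6)
        A, B = rng.normal(size=(37, 9)), rng.normal(size=(37, 6))
        np.testing.assert_allclose(
            cross_product(A, B, block_size), A.T @ B, atol=1e-6
        )

    def test_mismatched_feature_axis_rejected(self):
        with pytest.raises(ValidationError, match="shared feature"):
            cross_product(np.zeros((3, 2)), np.zeros((4, 2)))


class TestScaleFactors:
    def test_single_column_reduces_to_squared_norm(self):
        c = np.array([[1.0], [2.0], [2.0]])
        one = np.ones((1, 1))
        t0 = np.array([[1.0], [0.0], [0.0]])
        v0 = np.array([[0.0], [1.0], [0.0]])
        n_l, _ = compute_scale_factors(c, c, one, one, t0, v0)
        assert n_l == pytest.approx(9.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 3))
        U = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        S = np.linalg.qr(rng.normal(size=(3, 2)))[0]
        T = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        V = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        n_l, n_r = compute_scale_factors(X, Y, U, S, T, V)
        n_l2, n_r2 = compute_scale_factors(2 * X, Y, U, S, T, V)
        assert n_l2 == pytest.approx(4 * n_l)
        assert n_r2 == pytest.approx(n_r)

    def test_matches_explicit_frobenius_loops(self):
        rng = np.random.default_rng(8)
        X, Y = rng.normal(size=(6, 4)), rng.normal(size=(6, 3))
        U = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        S = np.linalg.qr(rng.normal(size=(3, 2)))[0]
        T = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        V = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        n_l, n_r = compute_scale_factors(X, Y, U, S, T, V)
        # brute-force Frobenius oracle
        left = X @ U @ S.T
        right = T @ V.T @ Y
        assert n_l == pytest.approx(sum(left[i, j] ** 2 for i in range(6) for j in range(3)))
        assert n_r == pytest.approx(sum(right[i, j] ** 2 for i in range(6) for j in range(3)))


# ---------------------------------------------------------------- Z update / objective


def _random_instance(seed, M=6, K=5, L=4, N=7, E=2):
    rng = np.random.default_rng(seed)
    X = _std(rng, (M, K))
    Y = _std(rng, (N, L))
    Z0 = rng.normal(size=(M, L))
    Z0 /= np.linalg.norm(Z0)
    U, S, *_ = fit_cca_pair(X, Z0, E)
    T, V, *_ = fit_cca_pair(Z0.T, Y.T, E)
    n_l, n_r = compute_scale_factors(X, Y, U, S, T, V)
    return X, Y, Z0, U, S, T, V, n_l, n_r


class TestUpdateFusion:
    @pytest.mark.parametrize("seed,alpha,lam", [(1, 0.3, 0.4), (2, 0.0, 1.0), (3, 0.7, 0.2)])
    def test_matches_explicit_loop_oracle(self, seed, alpha, lam):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(seed)
        Z = update_fusion_matrix(X, Y, U, S, T, V, Z0, alpha, lam, n_l, n_r)
        Zo = oracle_update_z(X, Y, U, S, T, V, Z0, alpha, lam, n_l, n_r)
        np.testing.assert_allclose(Z, Zo, atol=1e-10)
        assert abs(np.linalg.norm(Z) - 1) < 1e-10

    def test_alpha_near_one_returns_z0(self):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(4)
        alpha = 0.999
        Z = update_fusion_matrix(X, Y, U, S, T, V, Z0, alpha, 0.5, n_l, n_r)
        assert np.linalg.norm(Z - Z0) < 10 * (1 - alpha)

    def test_alpha_lambda_zero_isolates_x_term(self):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(5)
        Z = update_fusion_matrix(X, Y, U, S, T, V, Z0, 0.0, 0.0, n_l, n_r)
        expect = X @ U @ S.T / n_l
        np.testing.assert_allclose(Z, expect / np.linalg.norm(expect), atol=1e-12)

    def test_dimension_mismatch_names_term(self):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(6)
        with pytest.raises(ValidationError, match="X U S'"):
            update_fusion_matrix(X, Y, U, S, T, V, Z0[:, :-1], 0.1, 0.5, n_l, n_r)


class TestObjective:
    def test_penalty_vanishes_at_z0(self):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(7)
        with_pen = evaluate_objective(X, Y, Z0, Z0, U, S, T, V, 0.5, 0.5, n_l, n_r)
        # doubling alpha's penalty leaves the value at Z=Z0 proportional
        # to the trace part only
        trace_only = evaluate_objective(X, Y, Z0, Z0, U, S, T, V, 0.0, 0.5, n_l, n_r)
        assert with_pen == pytest.approx(0.5 * trace_only)

    def test_lambda_zero_ignores_y(self):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(8)
        rng = np.random.default_rng(0)
        f1 = evaluate_objective(X, Y, Z0, Z0, U, S, T, V, 0.2, 0.0, n_l, n_r)
        f2 = evaluate_objective(X, rng.normal(size=Y.shape), Z0, Z0, U, S, T, V, 0.2, 0.0, n_l, n_r)
        assert f1 == pytest.approx(f2)

    @pytest.mark.parametrize("seed", [9, 10])
    def test_matches_explicit_loop_oracle(self, seed):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(seed)
        rng = np.random.default_rng(seed + 100)
        Z = rng.normal(size=Z0.shape)
        Z /= np.linalg.norm(Z)
        f = evaluate_objective(X, Y, Z, Z0, U, S, T, V, 0.3, 0.6, n_l, n_r)
        fo = oracle_objective(X, Y, Z, Z0, U, S, T, V, 0.3, 0.6, n_l, n_r)
        assert f == pytest.approx(fo, abs=1e-10)

    def test_monitored_halves_the_penalty(self):
        X, Y, Z0, U, S, T, V, n_l, n_r = _random_instance(11)
        rng = np.random.default_rng(0)
        Z = rng.normal(size=Z0.shape)
        Z /= np.linalg.norm(Z)
        f_full = evaluate_objective(X, Y, Z, Z0, U, S, T, V, 0.4, 0.5, n_l, n_r)
        f_mon = monitored_objective(X, Y, Z, Z0, U, S, T, V, 0.4, 0.5, n_l, n_r)
        pen = np.linalg.norm(Z - Z0) ** 2
        assert f_mon - f_full == pytest.approx(0.2 * pen)


# ---------------------------------------------------------------- run_bicca


class TestRunBicca:
    def test_iteration0_equals_classical_cca(self, small_sim):
        X, Y, Z0, _ = small_sim
        res = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.2, lambda_=0.5, seed=1)
        Xs, keep = standardize_rows(X.values)
        Z0r = Z0.values[keep]
        Z0r = (Z0r - Z0r.mean(1, keepdims=True)) / Z0r.std(1, keepdims=True)
        Z0v = Z0r / np.linalg.norm(Z0r)
        U0, S0, *_ = fit_cca_pair(Xs, Z0v, 4)
        np.testing.assert_array_equal(res.iteration0.U, U0)
        np.testing.assert_array_equal(res.iteration0.S, S0)

    def test_alpha_boundary_keeps_z0_and_classical_embedding(self, small_sim):
        X, Y, Z0, _ = small_sim
        alpha = 0.99
        res = bicca.run_bicca(X, Y, Z0, E=4, alpha=alpha, lambda_=0.5, seed=1)
        Xs, keep = standardize_rows(X.values)
        Z0r = Z0.values[keep]
        Z0r = (Z0r - Z0r.mean(1, keepdims=True)) / Z0r.std(1, keepdims=True)
        Z0v = Z0r / np.linalg.norm(Z0r)
        assert np.linalg.norm(res.fusion.values - Z0v) < 2 * (1 - alpha)
        U0, S0, *_ = fit_cca_pair(Xs, Z0v, 4)
        assert np.abs(res.embedding.U - U0).max() < 0.05

    def test_objective_trace_monotone_on_noiseless_data(self, small_sim):
        X, Y, Z0, _ = small_sim
        res = bicca.run_bicca(X, Y, Z0, E=5, alpha=0.2, lambda_=0.5,
                              seed=11, tol=1e-12, max_iter=30)
        tr = np.array(res.objective_trace)
        assert np.all(np.diff(tr) >= -1e-9)
        assert len(tr) == res.iterations + 1

    def test_converges_before_max_iter(self, small_sim):
        X, Y, Z0, _ = small_sim
        res = bicca.run_bicca(X, Y, Z0, E=5, alpha=0.2, lambda_=0.5, seed=11)
        assert res.converged and res.iterations < 50

    def test_orthonormal_ccvs_and_unit_fusion(self, small_sim):
        X, Y, Z0, _ = small_sim
        res = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.1, lambda_=0.3, seed=2)
        for Mtx in (res.embedding.U, res.embedding.S, res.embedding.T, res.embedding.V):
            np.testing.assert_allclose(Mtx.T @ Mtx, np.eye(Mtx.shape[1]), atol=1e-8)
        assert abs(np.linalg.norm(res.fusion.values) - 1) < 1e-10

    def test_lowdim_agrees_with_full_up_to_rotation(self):
        X, Y, Z0, _ = bicca.simulate_paired(
            n_cells=40, n_types=3, M=60, N=70, E_true=4, noise_sd=0.3,
            corruption=0.3, seed=3,
        )
        full = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.1, lambda_=0.5, seed=3)
        low = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.1, lambda_=0.5, seed=3,
                              mode="lowdim", dims_lowdim=(12, 12))
        cf = np.vstack([full.embedding.U, full.embedding.S])
        cl = np.vstack([low.embedding.U, low.embedding.S])
        _, _, disparity = procrustes(cf, cl)
        assert disparity <= 0.05

    def test_block_size_does_not_change_the_result(self, small_sim):
        X, Y, Z0, _ = small_sim
        res_a = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.2, lambda_=0.5, seed=1, block_size=7)
        res_b = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.2, lambda_=0.5, seed=1, block_size=1000)
        np.testing.assert_allclose(res_a.embedding.U, res_b.embedding.U, atol=1e-6)
        np.testing.assert_allclose(res_a.fusion.values, res_b.fusion.values, atol=1e-6)

    def test_all_zero_cell_rejected(self):
        X, Y, Z0, _ = bicca.simulate_paired(n_cells=10, n_types=2, M=12, N=14,
                                            E_true=2, seed=1)
        vals = X.dense().copy()
        vals[:, 3] = 0.0
        Xbad = bicca.ModalityMatrix(vals, X.feature_ids, X.cell_ids)
        with pytest.raises(ValidationError, match="all-zero"):
            bicca.run_bicca(Xbad, Y, Z0, E=2)

    def test_constant_features_dropped_with_warning(self):
        X, Y, Z0, _ = bicca.simulate_paired(n_cells=12, n_types=2, M=15, N=16,
                                            E_true=2, noise_sd=0.2, seed=2)
        vals = X.dense().copy()
        vals[4, :] = 3.14
        Xc = bicca.ModalityMatrix(vals, X.feature_ids, X.cell_ids)
        with pytest.warns(UserWarning, match="constant"):
            res = bicca.run_bicca(Xc, Y, Z0, E=2, seed=2)
        assert X.feature_ids[4] not in res.feature_ids_x

    def test_invalid_parameters_rejected(self, small_sim):
        X, Y, Z0, _ = small_sim
        with pytest.raises(ValidationError):
            bicca.run_bicca(X, Y, Z0, E=4, alpha=1.0)
        with pytest.raises(ValidationError):
            bicca.run_bicca(X, Y, Z0, E=4, lambda_=1.5)


class TestImpute:
    def test_full_mode_is_final_z(self, small_sim):
        X, Y, Z0, _ = small_sim
        res = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.2, lambda_=0.5, seed=1)
        out = bicca.impute_fusion_profiles(res, X, Y)
        assert out is res.fusion

    def test_lowdim_alpha_boundary_tracks_z0(self):
        # uncorrupted initializer: Z0 lies in the span the initial CCA
        # captures, so the back-projection can reproduce it
        X, Y, Z0, _ = bicca.simulate_paired(n_cells=50, n_types=3, M=60, N=80,
                                            E_true=5, noise_sd=0.0,
                                            corruption=0.0, seed=11)
        res = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.99, lambda_=0.5, seed=1,
                              mode="lowdim", dims_lowdim=(10, 10))
        out = bicca.impute_fusion_profiles(res, X, Y, Z0)
        Z0r = Z0.values
        Z0r = (Z0r - Z0r.mean(1, keepdims=True)) / Z0r.std(1, keepdims=True)
        Z0v = Z0r / np.linalg.norm(Z0r)
        r = np.corrcoef(out.values.ravel(), Z0v.ravel())[0, 1]
        assert r > 0.95

    def test_noiseless_imputation_recovers_truth_per_cell(self, small_sim):
        # the back-projection imputation filters the corrupted part of
        # Z0 out of the profiles (it falls outside the CCA span)
        X, Y, Z0, truth = small_sim
        res = bicca.run_bicca(X, Y, Z0, E=4, alpha=0.1, lambda_=0.5, seed=1,
                              mode="lowdim", dims_lowdim=(12, 12))
        out = bicca.impute_fusion_profiles(res, X, Y, Z0)
        keep = np.isin(X.feature_ids, res.feature_ids_x)
        truth_prof = truth.x_profiles_y_cells[keep]
        # compare in the standardized feature space the solver works in
        truth_prof = (truth_prof - truth_prof.mean(1, keepdims=True)) / \
            truth_prof.std(1, keepdims=True)
        rs = [
            np.corrcoef(out.values[:, j], truth_prof[:, j])[0, 1]
            for j in range(out.values.shape[1])
        ]
        assert np.median(rs) >= 0.9
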