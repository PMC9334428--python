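"""Unit and property tests for the ICC agreement/consistency core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iccsync import icc
from conftest import anova_icc


class TestMomentMatrices:
    def test_identical_columns_give_rank_one_S_and_zero_V(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.tile(x[:, None], (1, 4))
        m = icc.moment_matrices(X)
        v = x.var()
        assert np.allclose(m.S, v * np.ones((4, 4)))
        assert np.allclose(m.V, 0.0, atol=1e-12)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        n, M = 240, 5
        X = rng.normal(size=(n, M))
        m = icc.moment_matrices(X)
        # brute-force double loop over subject pairs and time pairs
        mu = X.mean(axis=0)
        for i in range(M):
            for j in range(M):
                s_ij = np.mean((X[:, i] - mu[i]) * (X[:, j] - mu[j]))
                assert abs(m.S[i, j] - s_ij) < 1e-12
        nu = X.mean(axis=1)
        for k in range(0, n, 60):
            for l in range(0, n, 60):
                v_kl = np.mean((X[k] - nu[k]) * (X[l] - nu[l]))
                assert abs(m.V[k, l] - v_kl) < 1e-12
        assert abs(np.abs(m.S - np.diag(np.diag(m.S))).max()) < 0.25  # iid: near 0

    def test_mean_shift_moves_V_not_S(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X0 = np.column_stack([x, x])
        X1 = np.column_stack([x, x + 3.0])
        m0, m1 = icc.moment_matrices(X0), icc.moment_matrices(X1)
        assert np.allclose(m0.S, m1.S)
        assert m1.quad_V > m0.quad_V

    @pytest.mark.parametrize(
        "X",
        [
            np.ones((3, 4)),  # n too small
            np.ones((10, 1)),  # M too small
            np.column_stack([np.arange(10.0), np.full(10, 2.0)]),  # constant col
        ],
    )
    def test_degenerate_inputs_rejected(self, X):
        with pytest.raises(icc.DegenerateVoxelError):
            icc.moment_matrices(X)


class TestGammaRatio:
    def test_identical_columns_give_zero(self):
        x = np.sin(np.arange(40.0))
        m = icc.moment_matrices(np.tile(x[:, None], (1, 3)))
        g = icc.gamma_ratio(m, 40, 3)
        assert g.Gamma == pytest.approx(0.0, abs=1e-20)
        assert g.sigma_r2 == pytest.approx(m.V.mean())
        assert g.sigma_c2 == pytest.approx(m.S.mean())

    def test_increases_with_offset_variance(self):
        # columns = shared series + per-subject offsets of variance tau^2;
        # 1'V1/n^2 equals the between-subject variance of column time-means
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        offsets = rng.normal(size=5)
        gammas = []
        for tau in (0.0, 1.0, 2.0):
            X = x[:, None] + tau * offsets[None, :]
            m = icc.moment_matrices(X)
            g = icc.gamma_ratio(m, 60, 5)
            col_mean_var = (tau * offsets).var()  # population variance
            expected = (col_mean_var) / (m.quad_S / 25)
            assert g.Gamma == pytest.approx(expected, rel=1e-10)
            gammas.append(g.Gamma)
        assert gammas[0] < gammas[1] < gammas[2]

    def test_iid_noise_matches_monte_carlo_independence_level(self):
        # iid noise: E[1'V1/n^2] = (M-1)/(nM) and E[1'S1/M^2] = (n-1)/(nM),
        # so Gamma concentrates near (M-1)/(n-1)
        rng = np.random.default_rng(4)
        n, M = 240, 49
        vals = []
        for _ in range(500):
            X = rng.normal(size=(n, M))
            m = icc.moment_matrices(X)
            vals.append(icc.gamma_ratio(m, n, M).Gamma)
        assert np.mean(vals) == pytest.approx((M - 1) / (n - 1), rel=0.05)


class TestAgreementConsistency:
    def test_identical_columns_give_exact_one(self):
        x = np.cos(np.arange(25.0))
        X = np.tile(x[:, None], (1, 6))
        est = icc.icc_estimate(X)
        assert est.A_hat == pytest.approx(1.0, abs=1e-12)
        assert est.C_hat == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4)) + rng.normal(size=(30, 1))
        est = icc.icc_estimate(X)
        icc2k, icc3k = anova_icc(X)
        assert est.A_hat == pytest.approx(icc2k, abs=1e-10)
        assert est.C_hat == pytest.approx(icc3k, abs=1e-10)

    def test_subject_offsets_lower_A_but_not_C(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 5)) + rng.normal(size=(50, 1))
        off = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        est0 = icc.icc_estimate(X)
        est1 = icc.icc_estimate(X + off[None, :])
        assert est1.C_hat == pytest.approx(est0.C_hat, abs=1e-12)
        assert est1.A_hat < est0.A_hat

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_anova_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 241))
        M = int(rng.integers(2, 50))
        X = rng.normal(size=(n, M)) + 0.5 * rng.normal(size=(n, 1)) + rng.normal(
            size=(1, M)
        )
        est = icc.icc_estimate(X)
        icc2k, icc3k = anova_icc(X)
        assert abs(est.A_hat - icc2k) < 1e-8
        assert abs(est.C_hat - icc3k) < 1e-8
        assert est.A_hat <= 1.0 and est.C_hat <= 1.0
        if est.Gamma > 0:
            assert est.A_approx < est.C_hat
        assert est.var_A <= est.var_C + 1e-15

    def test_remainder_decays_with_n(self):
        # median |A_hat - A_approx| should drop by ~half when n doubles
        rng = np.random.default_rng(7)
        M = 5

        def med_remainder(n, reps=200):
            rem = []
            for _ in range(reps):
                X = rng.normal(size=(n, M)) + 0.8 * rng.normal(size=(n, 1)) \
                    + rng.normal(size=(1, M))
                rem.append(icc.icc_estimate(X).remainder_bound)
            return np.median(rem)

        m1, m2 = med_remainder(60), med_remainder(120)
        assert m2 <= 0.75 * m1


class TestSymmetryTransforms:
    @pytest.mark.parametrize("M", [2, 3, 6])
    def test_round_trip_identities(self, M):
        tf = icc.SymmetryTransforms(M)
        rng = np.random.default_rng(M)
        A = rng.normal(size=(M, M))
        A = A + A.T
        K, G = tf.elimination_matrix(), tf.duplication_matrix()
        assert np.allclose(K @ G, np.eye(tf.size))
        assert np.allclose(K @ A.flatten(order="F"), tf.vech(A))
        assert np.allclose(G @ tf.vech(A), A.flatten(order="F"))
        assert np.allclose(tf.unvech(tf.vech(A)), A)


class TestVariances:
    def test_symbolic_two_rater_identity_case(self):
        # M=2, Sigma = I: eta = (c*(t-a), 2*c*t, c*(t-a)) with a=2, t=2
        # -> derivative matrix D = [[0,1],[1,0]], Var(C) = (2/n) tr(D I D I) = 4/n
        n, M = 100, 2
        tf = icc.SymmetryTransforms(M)
        m = icc.MomentMatrices(
            S=np.eye(2), V=np.zeros((n, n)), trace_S=2.0, quad_S=2.0, quad_V=0.0
        )
        g = icc.gamma_ratio(m, n, M)
        eta, var_C, var_A = icc.icc_variances(m, g, n, M, tf)
        assert var_C == pytest.approx(4.0 / n, rel=1e-12)
        assert var_A == pytest.approx(var_C)  # gamma = 0
        assert np.allclose(eta, [0.0, 2.0, 0.0])

    @pytest.mark.parametrize("M", [3, 5, 8])
    def test_matches_dense_kronecker_evaluation(self, M):
        rng = np.random.default_rng(M)
        X = rng.normal(size=(80, M)) + 0.5 * rng.normal(size=(80, 1))
        m = icc.moment_matrices(X)
        g = icc.gamma_ratio(m, 80, M)
        tf = icc.SymmetryTransforms(M)
        eta, var_C, var_A = icc.icc_variances(m, g, 80, M, tf)
        K, G = tf.elimination_matrix(), tf.duplication_matrix()
        S = m.S
        a, t = S.sum(), np.trace(S)
        r = -a * np.eye(M).flatten(order="F") + t * np.ones(M * M)
        eta_dense = (M / ((M - 1) * a**2)) * (G.T @ r)
        var_dense = (2 / 80) * eta_dense @ K @ np.kron(S, S) @ K.T @ eta_dense
        assert np.allclose(eta, eta_dense)
        assert var_C == pytest.approx(var_dense, rel=1e-10)
        assert var_A == pytest.approx(var_dense * ((M - 1) / (M - 1 + g.Gamma)) ** 2)

    def test_monte_carlo_calibration_compound_symmetry(self):
        # empirical variance of C_hat over simulated Gaussian datasets
        rng = np.random.default_rng(11)
        n, M, rho = 240, 5, 0.5
        Sig = (1 - rho) * np.eye(M) + rho * np.ones((M, M))
        L = np.linalg.cholesky(Sig)
        X = rng.normal(size=(5000, n, M)) @ L.T
        res = icc.icc_map(X)
        assert res["var_C"].mean() == pytest.approx(res["C"].var(), rel=0.20)


class TestTStatistic:
    def test_zero_A_gives_zero_t(self):
        assert icc.t_statistic(0.0, 0.123) == 0.0

    def test_reported_supra_threshold_scale(self):
        # an agreement index of 0.243 with SE 0.0727 standardizes to ~3.34,
        # above the 2.7389 surrogate critical value reported at tail 0.05
        t = icc.t_statistic(0.243, 0.0727**2)
        assert t == pytest.approx(3.3425, abs=5e-4)
        assert t > 2.7389

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(icc.NumericalFailure):
            icc.t_statistic(0.5, 0.0)

    def test_matches_independent_recomputation_on_fixture(self, default_voxels):
        X = default_voxels[37]
        est = icc.icc_estimate(X)
        assert est.t_A == pytest.approx(est.A_hat / np.sqrt(est.var_A), rel=1e-14)


class TestBatchPath:
    def test_batch_matches_scalar_chain(self, default_voxels):
        sub = default_voxels[::97][:8]
        res = icc.icc_map(sub)
        for v in range(sub.shape[0]):
            est = icc.icc_estimate(sub[v])
            assert res["A"][v] == pytest.approx(est.A_hat, abs=1e-12)
            assert res["C"][v] == pytest.approx(est.C_hat, abs=1e-12)
            assert res["var_A"][v] == pytest.approx(est.var_A, rel=1e-10)
            assert res["t"][v] == pytest.approx(est.t_A, rel=1e-10)
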