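"""Kernel layer: ARD-RBF values, Kronecker oracle, Hadamard consistency."""

import numpy as np
import pytest

from momogp.kernels import (
    ArdKernelParams,
    ard_rbf,
    ard_rbf_backward,
    ard_rbf_raw,
    chol_with_jitter,
    cholesky_backward,
    coreg_cross_cov,
    coreg_kernel_full,
    coreg_kuu,
)


class TestArdRbf:
    def test_zero_distance_returns_variance(self):
        X = np.array([[0.0, 0.0]])
        K = ard_rbf(X, X, ArdKernelParams(2.5, [3.0, 0.7])).values
        assert np.allclose(K, [[2.5]])

    def test_zero_weight_removes_dimension(self):
        rng = np.random.default_rng(0)
        X, X2 = rng.normal(size=(4, 2)), rng.normal(size=(5, 2))
        K = ard_rbf(X, X2, ArdKernelParams(1.0, [0.0, 0.0])).values
        assert np.allclose(K, 1.0)

    def test_hand_evaluated_entry(self):
        # single pair at squared distance 1 with weight 2: exp(-0.5 * 2 * 1)
        K = ard_rbf(np.array([[0.0]]), np.array([[1.0]]),
                    ArdKernelParams(1.0, [2.0])).values
        assert np.allclose(K, [[np.exp(-1.0)]], atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            ard_rbf(np.zeros((3, 2)), np.zeros((3, 2)), ArdKernelParams(1.0, [1.0]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        X, X2 = rng.normal(size=(4, 3)), rng.normal(size=(6, 3))
        p = ArdKernelParams(1.3, [0.5, 2.0, 1.0])
        shift = rng.normal(size=3)
        assert np.allclose(ard_rbf(X, X2, p).values,
                           ard_rbf(X + shift, X2 + shift, p).values)

    def test_monotone_decreasing_in_distance(self):
        p = ArdKernelParams(1.0, [1.5])
        d = np.linspace(0, 3, 10)[:, None]
        K = ard_rbf(np.zeros((1, 1)), d, p).values[0]
        assert np.all(np.diff(K) < 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_square_kernel_symmetric_psd(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 2))
        p = ArdKernelParams(rng.uniform(0.5, 2), rng.uniform(0.1, 3, size=2))
        K = ard_rbf(X, X, p).values
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ArdKernelParams(-1.0, [1.0])
        with pytest.raises(ValueError):
            ArdKernelParams(1.0, [-0.5])


class TestKroneckerOracle:
    def test_scalar_one_gives_other_factor(self):
        KB = np.array([[1.0, 0.3], [0.3, 2.0]])
        assert np.allclose(coreg_kernel_full(np.array([[1.0]]), KB).values, KB)

    def test_identity_gives_block_diagonal(self):
        KB = np.array([[1.0, 0.5], [0.5, 1.0]])
        K = coreg_kernel_full(np.eye(2), KB).values
        assert np.allclose(K[:2, :2], KB)
        assert np.allclose(K[2:, 2:], KB)
        assert np.allclose(K[:2, 2:], 0)

    def test_eigenvalues_are_pairwise_products(self):
        rng = np.random.default_rng(2)
        Qa = rng.normal(size=(3, 3))
        Qb = rng.normal(size=(2, 2))
        KA, KB = Qa @ Qa.T, Qb @ Qb.T
        ev = np.sort(np.linalg.eigvalsh(coreg_kernel_full(KA, KB).values))
        expect = np.sort(np.outer(np.linalg.eigvalsh(KA),
                                  np.linalg.eigvalsh(KB)).ravel())
        assert np.allclose(ev, expect, rtol=1e-9, atol=1e-9)

    def test_size_guard_refuses_large_grids(self):
        with pytest.raises(ValueError, match="guard"):
            coreg_kernel_full(np.eye(101), np.eye(101))


class TestHadamardConsistency:
    """Matched-pair cross covariances must equal entries of the full Kronecker."""

    def test_single_pair_zero_distance(self):
        p1 = ArdKernelParams(1.0, [1.0])
        K = coreg_cross_cov(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.zeros((1, 1)), np.zeros((1, 1)), p1, p1).values
        assert np.allclose(K, [[1.0]])

    def test_zero_feature_variance_annihilates(self):
        rng = np.random.default_rng(3)
        pA = ArdKernelParams(1.2, [1.0, 0.4])
        pB = ArdKernelParams(0.0, [0.7])
        K = coreg_cross_cov(rng.normal(size=(5, 2)), rng.normal(size=(5, 1)),
                            rng.normal(size=(2, 2)), rng.normal(size=(2, 1)),
                            pA, pB).values
        assert np.allclose(K, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_kronecker_on_random_instances(self, seed):
        """K_uf and K_uu from elementwise products equal the corresponding
        entries of the (I*J) x (I*J) Kronecker kernel, for I,J<=6, m<=4."""
        rng = np.random.default_rng(seed)
        I, J = rng.integers(2, 7), rng.integers(2, 7)
        m = rng.integers(1, 5)
        r1, r2 = rng.integers(1, 4), rng.integers(1, 4)
        A = rng.normal(size=(I, r1))
        B = rng.normal(size=(J, r2))
        pA = ArdKernelParams(rng.uniform(0.5, 2), rng.uniform(0.2, 2, r1))
        pB = ArdKernelParams(rng.uniform(0.5, 2), rng.uniform(0.2, 2, r2))
        Kfull = coreg_kernel_full(ard_rbf(A, A, pA).values,
                                  ard_rbf(B, B, pB).values).values
        iu = rng.integers(0, I, size=m)
        ju = rng.integers(0, J, size=m)
        # cross-covariance against every grid entry, cell-major triples
        ti, tj = np.divmod(np.arange(I * J), J)
        Kuf = coreg_cross_cov(A[ti], B[tj], A[iu], B[ju], pA, pB).values
        rows = iu * J + ju
        assert np.allclose(Kuf, Kfull[rows, :], rtol=1e-10, atol=1e-12)
        Kuu = coreg_kuu(A[iu], B[ju], pA, pB, jitter=0.0).values
        assert np.allclose(Kuu, Kfull[np.ix_(rows, rows)], rtol=1e-10, atol=1e-12)

    def test_mismatched_inducing_counts_raise(self):
        p = ArdKernelParams(1.0, [1.0])
        with pytest.raises(ValueError, match="equal row counts"):
            coreg_cross_cov(np.zeros((2, 1)), np.zeros((2, 1)),
                            np.zeros((3, 1)), np.zeros((2, 1)), p, p)


class TestNumericalBackward:
    """The hand-written reverse-mode pieces against finite differences."""

    def test_rbf_backward_matches_fd(self):
        rng = np.random.default_rng(7)
        X, X2 = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
        var, w = 1.3, np.array([0.8, 1.7])
        Kbar = rng.normal(size=(4, 3))
        K = ard_rbf_raw(X, X2, var, w)
        gX, gX2, gvar, gw = ard_rbf_backward(X, X2, var, w, K, Kbar)
        eps = 1e-6

        def obj(X_, X2_, var_, w_):
            return float((Kbar * ard_rbf_raw(X_, X2_, var_, w_)).sum())

        for arr, g in ((X, gX), (X2, gX2), (w, gw)):
            flat = arr.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = obj(X, X2, var, w)
                flat[idx] = orig - eps
                lo = obj(X, X2, var, w)
                flat[idx] = orig
                assert np.isclose(np.ravel(g)[idx], (hi - lo) / (2 * eps),
                                  rtol=1e-5, atol=1e-8)
        hi = obj(X, X2, var + eps, w)
        lo = obj(X, X2, var - eps, w)
        assert np.isclose(gvar, (hi - lo) / (2 * eps), rtol=1e-5)

    def test_cholesky_backward_matches_fd(self):
        rng = np.random.default_rng(8)
        Q = rng.normal(size=(4, 4))
        K = Q @ Q.T + 4 * np.eye(4)
        Lbar = rng.normal(size=(4, 4))
        L = np.linalg.cholesky(K)
        Kbar = cholesky_backward(L, Lbar)
        eps = 1e-6
        for a in range(4):
            for b in range(a + 1):  # symmetric perturbations
                E = np.zeros((4, 4))
                E[a, b] = E[b, a] = 1.0
                hi = float((np.tril(Lbar) * np.linalg.cholesky(K + eps * E)).sum())
                lo = float((np.tril(Lbar) * np.linalg.cholesky(K - eps * E)).sum())
                fd = (hi - lo) / (2 * eps)
                got = Kbar[a, b] + Kbar[b, a] if a != b else Kbar[a, a]
                assert np.isclose(got, fd, rtol=1e-5, atol=1e-8)

    def test_jitter_escalation_recovers_near_singular(self):
        K = np.ones((3, 3))  # rank one, needs jitter
        L, jit = chol_with_jitter(K, 1e-6)
        assert np.all(np.isfinite(L))
        assert jit <= 1e-4
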