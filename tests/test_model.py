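"""Single-view model: init, ELBO bound, gradients, training, prediction."""

import numpy as np
import pytest

from momogp.data import ViewMatrix, build_triple_store
from momogp.model import (
    TrainConfig,
    elbo,
    elbo_and_grads,
    fit,
    init_model,
    load_model,
    log_marginal_exact,
    optimize_q_analytic,
    predict_mean_var,
    save_model,
    set_full_grid_inducing,
)


def make_store(I, J, seed=0):
    rng = np.random.default_rng(seed)
    view = ViewMatrix(rng.normal(size=(I, J)),
                      [f"c{i}" for i in range(I)], [f"g{j}" for j in range(J)])
    return build_triple_store(view)


def randomized_model(I, J, r1, r2, m, seed=0, jolt=0.3):
    """Init + random parameter perturbation (nontrivial kernels and q).

    Per-dimension feature weights are untied so finite differences can probe
    each weight independently.
    """
    model = init_model(I, J, r1, r2, m, seed=seed, isotropic_features=False)
    rng = np.random.default_rng(seed + 100)
    for k in model.params:
        model.params[k] = model.params[k] + rng.normal(0, jolt, size=np.shape(model.params[k]))
    return model


class TestInit:
    def test_same_seed_bit_identical(self):
        a = init_model(30, 10, 2, 2, 5, seed=4)
        b = init_model(30, 10, 2, 2, 5, seed=4)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])
        assert np.array_equal(a.inducing_cell_indices, b.inducing_cell_indices)

    def test_shapes(self):
        model = init_model(100, 20, 2, 3, 7, seed=0)
        assert model.params["A"].shape == (100, 2)
        assert model.params["B0"].shape == (20, 3)
        assert model.cell_embedding.table.shape == (100, 2)
        assert model.kernel_cells().ard_weights.shape == (2,)
        assert model.variational().q_sqrt.shape == (7, 7)

    def test_m_equals_sizes_gives_permutations(self):
        model = init_model(6, 6, 2, 2, 6, seed=1)
        assert sorted(model.inducing_cell_indices) == list(range(6))
        assert sorted(model.inducing(0).feature_indices) == list(range(6))

    def test_m_too_large_rejected(self):
        with pytest.raises(ValueError, match="m="):
            init_model(5, 10, 2, 2, 6, seed=0)


class TestElbo:
    def test_empty_batch_rejected(self):
        model = init_model(4, 3, 2, 2, 3, seed=0)
        store = make_store(4, 3)
        empty = type(store)(np.array([], dtype=int), np.array([], dtype=int),
                            np.array([]), 4, 3)
        with pytest.raises(ValueError, match="non-empty"):
            elbo(model, empty)

    def test_kl_zero_when_q_equals_whitened_prior(self):
        """At q_mu=0, q_sqrt=I the KL vanishes: the ELBO equals the expected
        log-likelihood term, recomputed here densely as an oracle."""
        from scipy.linalg import solve_triangular
        from momogp.kernels import ard_rbf_raw, JITTER
        model = randomized_model(5, 4, 2, 2, 4, seed=2)
        model.params["q_mu0"] = np.zeros(4)
        model.params["q_raw0"] = np.zeros((4, 4))
        store = make_store(5, 4, seed=2)

        A, B = model.params["A"], model.params["B0"]
        pa, pb = model.kernel_cells(), model.kernel_features()
        s2 = model.variational().noise_variance
        Au = A[model.inducing_cell_indices]
        Bu = B[model.inducing(0).feature_indices]
        Kuu = (ard_rbf_raw(Au, Au, pa.variance, pa.ard_weights)
               * ard_rbf_raw(Bu, Bu, pb.variance, pb.ard_weights)
               + JITTER * pa.variance * pb.variance * np.eye(4))
        L = np.linalg.cholesky(Kuu)
        Kuf = (ard_rbf_raw(Au, A[store.i], pa.variance, pa.ard_weights)
               * ard_rbf_raw(Bu, B[store.j], pb.variance, pb.ard_weights))
        al = solve_triangular(L, Kuf, lower=True)
        # q = whitened prior: mean 0, marginal var = kff (Nystrom deficit cancels)
        vq = pa.variance * pb.variance - (al ** 2).sum(0) + (al ** 2).sum(0)
        expect = (-0.5 * len(store) * np.log(2 * np.pi * s2)
                  - 0.5 * (store.y @ store.y + vq.sum()) / s2)
        assert np.isclose(elbo(model, store), expect, rtol=1e-10)

    def test_elbo_lower_bounds_exact_marginal(self):
        """Sparse bound <= dense Kronecker-GP log marginal on a 3x2 toy,
        with m=3 matched pairs (feature indices repeat since J=2)."""
        from momogp.model import set_inducing_pairs
        store = make_store(3, 2, seed=5)
        model = randomized_model(3, 2, 2, 2, 2, seed=5)
        set_inducing_pairs(model, [0, 1, 2], [0, 1, 0])
        assert elbo(model, store) <= log_marginal_exact(model, store) + 1e-9

    def test_bound_tight_with_full_grid_and_optimal_q(self):
        store = make_store(3, 2, seed=6)
        model = randomized_model(3, 2, 2, 2, 2, seed=6)
        set_full_grid_inducing(model)
        model = optimize_q_analytic(model, store)
        gap = log_marginal_exact(model, store) - elbo(model, store)
        assert 0 <= gap < 1e-3

    def test_batch_order_invariance(self):
        store = make_store(6, 4, seed=7)
        model = randomized_model(6, 4, 2, 2, 4, seed=7)
        perm = np.random.default_rng(0).permutation(len(store))
        shuffled = type(store)(store.i[perm], store.j[perm], store.y[perm], 6, 4)
        assert np.isclose(elbo(model, store), elbo(model, shuffled), rtol=1e-12)

    def test_minibatch_scaling_is_unbiased_at_uniform_batches(self):
        """Mean of per-batch ELBO likelihood terms over a partition equals the
        full-batch value (the batch-independent KL is subtracted each time)."""
        store = make_store(6, 4, seed=8)
        model = randomized_model(6, 4, 2, 2, 4, seed=8)
        full = elbo(model, store)
        halves = []
        for sel in (np.arange(12), np.arange(12, 24)):
            sub = type(store)(store.i[sel], store.j[sel], store.y[sel], 6, 4)
            halves.append(elbo(model, sub, total_n=24))
        assert np.isclose(np.mean(halves), full, rtol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("seed", range(2))
    def test_all_gradients_match_finite_differences(self, seed):
        store = make_store(6, 5, seed=seed)
        model = randomized_model(6, 5, 2, 3, 4, seed=seed)
        val, grads = elbo_and_grads(model, store)
        assert np.isfinite(val)
        eps = 1e-6
        rng = np.random.default_rng(seed)
        for k in sorted(model.params):
            shape = np.shape(model.params[k])
            flat = np.array(model.params[k], dtype=float).reshape(-1)
            idxs = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for idx in idxs:
                if k.startswith("q_raw"):
                    r, c = np.unravel_index(idx, shape)
                    if c > r:  # upper triangle is inert storage
                        continue
                orig = flat[idx]
                flat[idx] = orig + eps
                model.params[k] = flat.reshape(shape)
                hi = elbo(model, store)
                flat[idx] = orig - eps
                model.params[k] = flat.reshape(shape)
                lo = elbo(model, store)
                flat[idx] = orig
                model.params[k] = flat.reshape(shape)
                fd = (hi - lo) / (2 * eps)
                ga = np.asarray(grads[k]).reshape(-1)[idx]
                assert np.isclose(ga, fd, rtol=1e-4, atol=1e-7), (k, idx, ga, fd)


class TestFit:
    def test_fullbatch_smoothed_elbo_nondecreasing(self):
        """10-epoch means of the full-batch ELBO trace never drop (tol 1e-3)
        on a 20x10 synthetic matrix."""
        from momogp.simulate import SimulationConfig, simulate
        views, _ = simulate(SimulationConfig(I=20, feature_counts=[10],
                                             n_cell_clusters=2, feature_blocks=2,
                                             r1=2, r2=2, seed=0))
        store = build_triple_store(views[0])
        model = init_model(20, 10, 2, 2, 10, seed=0)
        trained = fit(model, store, TrainConfig(epochs=100, batch_size=len(store),
                                                learning_rate=1e-2, seed=0))
        trace = np.array([rec["elbo"] for rec in trained.training_log])
        means = trace.reshape(10, 10).mean(axis=1)
        assert np.all(np.diff(means) >= -1e-3)

    def test_identical_seeds_identical_traces(self):
        store = make_store(10, 6, seed=1)
        cfg = TrainConfig(epochs=8, batch_size=16, learning_rate=1e-2, seed=3)
        t1 = fit(init_model(10, 6, 2, 2, 5, seed=9), store, cfg)
        t2 = fit(init_model(10, 6, 2, 2, 5, seed=9), store, cfg)
        assert [r["elbo"] for r in t1.training_log] == [r["elbo"] for r in t2.training_log]
        for k in t1.params:
            assert np.array_equal(t1.params[k], t2.params[k])

    def test_nonfinite_elbo_aborts(self):
        store = make_store(5, 4, seed=2)
        model = init_model(5, 4, 2, 2, 3, seed=2)
        model.params["log_noise0"] = np.asarray(-2000.0)  # noise -> 0 underflow
        with pytest.raises((FloatingPointError, np.linalg.LinAlgError)):
            fit(model, store, TrainConfig(epochs=2, batch_size=20, seed=0))

    def test_wrong_store_shape_rejected(self):
        model = init_model(5, 4, 2, 2, 3, seed=0)
        with pytest.raises(ValueError, match="features"):
            fit(model, make_store(5, 6), TrainConfig(epochs=1))


class TestPredict:
    def test_variances_nonnegative(self):
        model = randomized_model(8, 5, 2, 2, 5, seed=3)
        _, var = predict_mean_var(model, np.arange(8), np.arange(5))
        assert np.all(var >= 0)

    def test_out_of_range_rejected(self):
        model = init_model(4, 3, 2, 2, 3, seed=0)
        with pytest.raises(ValueError, match="out of range"):
            predict_mean_var(model, [7], [0])

    def test_matches_exact_posterior_with_full_grid_inducing(self):
        """With inducing pairs on every grid point and the optimal q, the
        sparse posterior equals the dense Kronecker-GP posterior."""
        from momogp.kernels import ard_rbf_raw
        store = make_store(3, 2, seed=4)
        model = randomized_model(3, 2, 2, 2, 2, seed=4)
        set_full_grid_inducing(model)
        model = optimize_q_analytic(model, store)
        mean, var = predict_mean_var(model, np.arange(3), np.arange(2))

        # dense oracle
        A, B = model.params["A"], model.params["B0"]
        pa, pb = model.kernel_cells(), model.kernel_features()
        s2 = model.variational().noise_variance
        Xa, Xb = A[store.i], B[store.j]
        K = (ard_rbf_raw(Xa, Xa, pa.variance, pa.ard_weights)
             * ard_rbf_raw(Xb, Xb, pb.variance, pb.ard_weights))
        Kinv = np.linalg.inv(K + s2 * np.eye(6))
        mean_oracle = (K @ Kinv @ store.y).reshape(3, 2)
        var_oracle = np.diag(K - K @ Kinv @ K).reshape(3, 2)
        assert np.allclose(mean, mean_oracle, atol=1e-4)
        assert np.allclose(var, var_oracle, atol=1e-4)

    def test_interpolation_limit_small_noise(self):
        """With tiny noise, dense inducing coverage and optimal q, posterior
        means at observed pairs reproduce the observations."""
        store = make_store(3, 2, seed=9)
        model = randomized_model(3, 2, 2, 2, 2, seed=9, jolt=0.2)
        model.params["log_noise0"] = np.asarray(np.log(1e-6))
        set_full_grid_inducing(model)
        model = optimize_q_analytic(model, store)
        mean, _ = predict_mean_var(model, np.arange(3), np.arange(2))
        assert np.allclose(mean.ravel(), store.y, atol=1e-2)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        model = randomized_model(6, 4, 2, 2, 3, seed=1)
        save_model(model, str(tmp_path / "ckpt"))
        back = load_model(str(tmp_path / "ckpt"))
        store = make_store(6, 4, seed=1)
        assert np.isclose(elbo(model, store), elbo(back, store), rtol=1e-12)
        for k in model.params:
            assert np.allclose(model.params[k], back.params[k])
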