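"""Canned validation experiments for the model family.

Each function sets up a self-contained experiment on synthetic data --
exact-oracle consistency, bound tightness, optimization sanity, parameter
recovery, shared/private dimension recovery, relevance correctness, metric
correctness, and the linear-time scaling property -- and returns the measured
quantities.  They are the package's own reproducibility suite: the test suite
asserts on their outputs, and the results script re-runs them from scratch.

All randomness is derived from the single ``seed`` argument.
"""

from __future__ import annotations

import time

import numpy as np

from .data import ViewMatrix, build_triple_store  # noqa: F401 (ViewMatrix used below)
from .evaluation import (adjusted_rand_index, cluster_embedding,
                         clustering_accuracy)
from .interpret import (cluster_features, feature_relevance,
                        link_metagene_to_cells, majority_celltype,
                        relevance_map)
from .kernels import ArdKernelParams, ard_rbf, coreg_cross_cov, coreg_kernel_full, coreg_kuu
from .model import (TrainConfig, elbo, fit, fit_views, init_model,
                    init_multi_model, log_marginal_exact, optimize_q_analytic,
                    posterior_mean_at_latent, set_full_grid_inducing)
from .multiview import (default_delta, effective_ard_weights,
                        partition_dimensions)
from .simulate import SimulationConfig, make_marker_toy, simulate


# ---------------------------------------------------------------------------
# kernel-layer consistency
# ---------------------------------------------------------------------------

def kronecker_consistency(seed: int, n_instances: int = 25) -> dict:
    """Max relative error between matched-pair Hadamard covariances and the
    corresponding entries of the full Kronecker kernel (I, J <= 6, m <= 4)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        I, J = rng.integers(2, 7), rng.integers(2, 7)
        m = int(rng.integers(1, 5))
        r1, r2 = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        A, B = rng.normal(size=(I, r1)), rng.normal(size=(J, r2))
        pA = ArdKernelParams(rng.uniform(0.5, 2), rng.uniform(0.2, 2, r1))
        pB = ArdKernelParams(rng.uniform(0.5, 2), rng.uniform(0.2, 2, r2))
        Kfull = coreg_kernel_full(ard_rbf(A, A, pA).values,
                                  ard_rbf(B, B, pB).values).values
        iu = rng.integers(0, I, size=m)
        ju = rng.integers(0, J, size=m)
        ti, tj = np.divmod(np.arange(I * J), J)
        Kuf = coreg_cross_cov(A[ti], B[tj], A[iu], B[ju], pA, pB).values
        Kuu = coreg_kuu(A[iu], B[ju], pA, pB, jitter=0.0).values
        ref_uf = Kfull[iu * J + ju, :]
        ref_uu = Kfull[np.ix_(iu * J + ju, iu * J + ju)]
        scale = max(np.abs(Kfull).max(), 1e-300)
        worst = max(worst,
                    float(np.abs(Kuf - ref_uf).max() / scale),
                    float(np.abs(Kuu - ref_uu).max() / scale))
    return {"max_rel_err": worst, "n": n_instances}


# ---------------------------------------------------------------------------
# ELBO bound against the dense GP
# ---------------------------------------------------------------------------

def elbo_bound_gap(seed: int) -> dict:
    """On a 3x2 toy with inducing pairs on every grid point: the sparse bound
    must stay below the exact log marginal, and with the optimal q the gap
    closes to ~jitter level."""
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(3, 2))
    view = ViewMatrix(Y, [f"c{i}" for i in range(3)], ["g0", "g1"])
    store = build_triple_store(view)
    model = init_model(3, 2, 2, 2, 2, seed=seed)
    for k in model.params:
        model.params[k] = model.params[k] + rng.normal(0, 0.4, size=np.shape(model.params[k]))
    set_full_grid_inducing(model)
    exact = log_marginal_exact(model, store)
    below_prior_q = elbo(model, store)
    model = optimize_q_analytic(model, store)
    tight = elbo(model, store)
    return {
        "exact_log_marginal": exact,
        "elbo_prior_q": below_prior_q,
        "elbo_optimal_q": tight,
        "gap": exact - tight,
        "bound_violation": max(0.0, tight - exact, below_prior_q - exact),
        "n": len(store),
    }


# ---------------------------------------------------------------------------
# optimization sanity
# ---------------------------------------------------------------------------

def training_sanity(seed: int, epochs: int = 100) -> dict:
    """Full-batch training on a 20x10 draw from the model: 10-epoch means of
    the ELBO trace must be non-decreasing, and reruns bit-reproducible."""
    views, _ = simulate(SimulationConfig(I=20, feature_counts=[10], r1=2, r2=2,
                                         n_cell_clusters=2, feature_blocks=2,
                                         seed=seed))
    store = build_triple_store(views[0])
    cfg = TrainConfig(epochs=epochs, batch_size=len(store), learning_rate=1e-2,
                      seed=seed)
    t1 = fit(init_model(20, 10, 2, 2, 10, seed=seed), store, cfg)
    t2 = fit(init_model(20, 10, 2, 2, 10, seed=seed), store, cfg)
    trace = np.array([r["elbo"] for r in t1.training_log])
    means = trace.reshape(-1, 10).mean(axis=1)
    max_drop = float(np.maximum(0.0, -np.diff(means)).max())
    rerun_diff = float(abs(t1.training_log[-1]["elbo"] - t2.training_log[-1]["elbo"]))
    return {"max_drop_10epoch_means": max_drop, "rerun_elbo_diff": rerun_diff,
            "final_elbo": float(trace[-1]), "n": len(store)}


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

#: training protocol for the recovery-scale experiments
RECOVERY_EPOCHS = 500
RECOVERY_LR = 0.02
RECOVERY_RESTARTS = 3


def _fit_best_of(store, I, J, r1, r2, m, base_seed, restarts=RECOVERY_RESTARTS,
                 epochs=RECOVERY_EPOCHS):
    """Fit with several random initializations, keep the best full-batch ELBO
    (the model's own objective; no ground truth involved)."""
    best = None
    for k in range(restarts):
        s = int(base_seed + 1000 * k) % (2 ** 31)
        model = init_model(I, J, r1, r2, m, seed=s)
        trained = fit(model, store, TrainConfig(
            epochs=epochs, batch_size=2048, learning_rate=RECOVERY_LR,
            seed=s, analytic_q_every=75))
        e = elbo(trained, store)
        if best is None or e > best[0]:
            best = (e, trained)
    return best[1]


def recovery_experiment(seed: int, n_seeds: int = 3) -> dict:
    """Cluster recovery from data simulated by the model itself.

    300 cells in 3 latent clusters (r1=2), 40 features; fit, then GMM-cluster
    the learned cell embedding and score ARI against the generative labels,
    averaged over ``n_seeds`` data draws.
    """
    from scipy.spatial.distance import pdist
    from scipy.stats import spearmanr

    aris, spearmans = [], []
    for k in range(n_seeds):
        dseed = int(seed + k) % (2 ** 31)
        views, truth = simulate(SimulationConfig(I=300, feature_counts=[40],
                                                 r1=2, r2=3, n_cell_clusters=3,
                                                 feature_blocks=4, seed=dseed))
        store = build_triple_store(views[0])
        trained = _fit_best_of(store, 300, 40, 2, 3, 40, dseed)
        A = trained.params["A"]
        res = cluster_embedding(A, 3, algorithm="gmm", seed=0)
        aris.append(adjusted_rand_index(res, truth.cell_cluster_labels))
        # GP-LVM distance preservation: far in data space => far in latent space
        spearmans.append(float(spearmanr(pdist(views[0].values), pdist(A)).statistic))
    return {"ari_mean": float(np.mean(aris)), "ari_per_seed": aris,
            "distance_spearman_mean": float(np.mean(spearmans)),
            "n": 300 * 40 * n_seeds}


# ---------------------------------------------------------------------------
# MRD shared/private recovery
# ---------------------------------------------------------------------------

def mrd_experiment(seed: int, n_seeds: int = 5) -> dict:
    """Two views over shared cells with one private dimension each plus one
    shared dimension; success = the delta-rule partition of the learned
    (scale-adjusted) ARD weights matches the generative pattern.

    Latent dimensions of the model are identifiable only up to permutation,
    so the comparison is on the multiset of dimension labels.
    """
    want = sorted(["private_view0", "shared", "private_view1"])
    successes, patterns = 0, []
    for k in range(n_seeds):
        dseed = int(seed + k) % (2 ** 31)
        views, truth = simulate(SimulationConfig(
            I=300, feature_counts=[50, 50], r1=3, r2=3, feature_blocks=4,
            independent_dims=True, activity=[[1, 1, 0], [0, 1, 1]], seed=dseed))
        stores = [build_triple_store(v) for v in views]
        model = init_multi_model(300, [50, 50], 3, 3, 40, seed=dseed)
        model = fit_views(model, stores, TrainConfig(
            epochs=RECOVERY_EPOCHS, batch_size=2048, learning_rate=RECOVERY_LR,
            seed=dseed, analytic_q_every=75))
        W = effective_ard_weights(model)
        part = partition_dimensions(W, default_delta(W))
        got = sorted([part.label(r) for r in range(3)])
        patterns.append(got)
        successes += int(got == want)
    return {"success_rate": successes / n_seeds, "n_success": successes,
            "patterns": patterns, "n": n_seeds}


# ---------------------------------------------------------------------------
# relevance correctness
# ---------------------------------------------------------------------------

def relevance_gradient_check(seed: int, n_checks: int = 12) -> dict:
    """Analytic relevance gradients vs central finite differences (step 1e-4)
    on a randomized model."""
    rng = np.random.default_rng(seed)
    model = init_model(10, 8, 2, 2, 6, seed=seed)
    for k in model.params:
        model.params[k] = model.params[k] + rng.normal(0, 0.4, size=np.shape(model.params[k]))
    eps = 1e-4
    worst = 0.0
    A = model.params["A"]
    for _ in range(n_checks):
        i = int(rng.integers(0, 10))
        j = int(rng.integers(0, 8))
        analytic = feature_relevance(model, [j], [i], scale=False)[0]
        g = np.zeros(model.r1)
        for r in range(model.r1):
            hi_a, lo_a = A[i].copy(), A[i].copy()
            hi_a[r] += eps
            lo_a[r] -= eps
            hi = posterior_mean_at_latent(model, hi_a, [j])[0]
            lo = posterior_mean_at_latent(model, lo_a, [j])[0]
            g[r] = (hi - lo) / (2 * eps)
        fd = float(np.linalg.norm(g))
        worst = max(worst, abs(analytic - fd) / max(abs(fd), 1e-12))
    return {"max_rel_err": worst, "n": n_checks}


def marker_pipeline(seed: int, tau: float = 30.0) -> dict:
    """End-to-end interpretation on the planted marker toy.

    Fit a single-view model on the (feature-centered) toy, cluster the
    learned feature embedding into metagenes, compute each metagene's
    relevance map, link cells at tau, and check that each marker block's
    metagene links to a cell set dominated by its planted cell type.

    Features are centered before fitting because the GP prior has zero mean:
    a common positive baseline would otherwise have to be explained as
    between-cell correlation, which blurs the embedding geometry.  Relevance
    localization also needs enough inducing capacity for the learned type
    regions to decorrelate, hence the relatively large m here.
    """
    n_types, mpt, cpt = 2, 40, 60
    view, labels, marker_map = make_marker_toy(n_types=n_types,
                                               markers_per_type=mpt,
                                               cells_per_type=cpt,
                                               n_background=8, effect=0.5,
                                               grade=2.5, noise_sd=0.3,
                                               seed=seed)
    centered = view.values - view.values.mean(axis=0, keepdims=True)
    view = ViewMatrix(centered, view.cell_ids, view.feature_ids, view.view_name)
    store = build_triple_store(view)
    I, J = view.n_cells, view.n_features
    trained = _fit_best_of(store, I, J, 2, 2, 88, seed, restarts=1)
    lab = labels.for_cells(view.cell_ids)

    # one metagene per marker block plus one for the unstructured background
    assign = cluster_features(trained.feature_embedding(0), G=n_types + 1, seed=0)
    rmap = relevance_map(trained, assign, tau=tau)
    fid = {f: k for k, f in enumerate(view.feature_ids)}
    coverages = {}
    for ctype, feats in marker_map.items():
        cols = {fid[f] for f in feats}
        # the metagene holding the majority of this block's markers
        gids, cnt = np.unique(assign.assignment[list(cols)], return_counts=True)
        g = int(gids[np.argmax(cnt)])
        cells = link_metagene_to_cells(rmap, g, tau)
        if cells.size == 0:
            coverages[ctype] = 0.0
            continue
        top, cov = majority_celltype(cells, lab)
        coverages[ctype] = cov if top == ctype else 0.0
    return {"min_coverage_pct": float(min(coverages.values())),
            "coverage_per_type": coverages, "n": I * J}


# ---------------------------------------------------------------------------
# metric correctness
# ---------------------------------------------------------------------------

def metrics_oracle_check(seed: int, n_instances: int = 30) -> dict:
    """ACC and ARI against brute-force re-computation on small instances."""
    import itertools
    rng = np.random.default_rng(seed)
    max_acc_diff = max_ari_diff = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 13))
        labels = rng.choice(list("ABCD"), size=n)
        assign = rng.integers(0, 3, size=n)
        # ACC oracle
        correct = 0
        for c in set(assign.tolist()):
            members = [labels[t] for t in range(n) if assign[t] == c]
            modal = min(sorted(set(members)), key=lambda s: (-members.count(s), s))
            correct += sum(1 for x in members if x == modal)
        acc_oracle = 100.0 * correct / n
        max_acc_diff = max(max_acc_diff,
                           abs(clustering_accuracy(assign, labels) - acc_oracle))
        # ARI oracle by pair counting
        pairs = list(itertools.combinations(range(n), 2))
        n11 = sum(1 for i, j in pairs if assign[i] == assign[j] and labels[i] == labels[j])
        n00 = sum(1 for i, j in pairs if assign[i] != assign[j] and labels[i] != labels[j])
        n10 = sum(1 for i, j in pairs if assign[i] == assign[j] and labels[i] != labels[j])
        n01 = sum(1 for i, j in pairs if assign[i] != assign[j] and labels[i] == labels[j])
        ri = (n11 + n00) / len(pairs)
        exp = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / len(pairs) ** 2
        mx = (2 * n11 + n10 + n01 + 2 * n00 + n10 + n01) / (2 * len(pairs))
        ari_oracle = 1.0 if mx == exp else (ri - exp) / (mx - exp)
        max_ari_diff = max(max_ari_diff,
                           abs(adjusted_rand_index(assign, labels) - ari_oracle))
    ident = np.array([0, 0, 1, 1, 2, 2])
    ident_labels = np.array(list("AABBCC"))
    return {
        "max_acc_abs_diff": max_acc_diff,
        "max_ari_abs_diff": max_ari_diff,
        "acc_identical_partitions": clustering_accuracy(ident, ident_labels),
        "ari_identical_partitions": adjusted_rand_index(ident, ident_labels),
        "n": n_instances,
    }


# ---------------------------------------------------------------------------
# linear scaling
# ---------------------------------------------------------------------------

def scaling_slope(seed: int, sizes=(2000, 4000, 8000), m: int = 40,
                  reps: int = 5, batch_size: int = 512) -> dict:
    """Log-log slope of per-epoch wall time against the number of triples at
    fixed m (linear-time property; relative timing only).

    Benchmarking hygiene: measurements of the different sizes are interleaved
    round-robin (so drifting machine state hits all sizes alike) and the
    minimum over repetitions is used (wall-time noise is strictly additive).
    """
    setups = []
    for n_triples in sizes:
        J = 50
        I = n_triples // J
        views, _ = simulate(SimulationConfig(I=I, feature_counts=[J], r1=2, r2=3,
                                             n_cell_clusters=3, feature_blocks=4,
                                             seed=seed))
        store = build_triple_store(views[0])
        model = init_model(I, J, 2, 3, m, seed=seed)
        fit(model, store, TrainConfig(epochs=1, batch_size=batch_size, seed=seed))  # warm-up
        setups.append((model, store))
    cfg = TrainConfig(epochs=5, batch_size=batch_size, learning_rate=1e-2, seed=seed)
    best = [np.inf] * len(sizes)
    for _ in range(reps):
        for k, (model, store) in enumerate(setups):
            t0 = time.perf_counter()
            fit(model, store, cfg)
            best[k] = min(best[k], (time.perf_counter() - t0) / cfg.epochs)
    slope = float(np.polyfit(np.log(np.asarray(sizes, float)),
                             np.log(np.asarray(best)), 1)[0])
    return {"slope": slope, "sizes": list(sizes),
            "epoch_seconds": [float(t) for t in best], "n": max(sizes)}
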