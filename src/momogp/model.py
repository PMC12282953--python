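"""Multi-output GP-LVM with matched inducing pairs: model state, ELBO, training.

The generative model for one view: cells i and features j carry trainable
latent coordinates a_i (shared across views) and b_j (per view), produced by a
plain embedding layer (index -> dense vector lookup).  The latent function
value for grid entry (i, j) has a zero-mean GP prior whose covariance is the
product kernel k_A(a_i, a_i') * k_B(b_j, b_j') -- the Kronecker
(coregionalization) kernel over the vectorized grid -- and the observation
y_ij = f_ij + Gaussian noise.

Inference is sparse stochastic variational GP regression: m inducing *pairs*
(a_u, b_u), a whitened Gaussian q(u) with mean ``q_mu`` and lower-triangular
scale ``q_sqrt``, and the standard evidence lower bound

    ELBO = (N / |batch|) * E_q [ log N(y_t | mu_t, sigma^2) terms ] - KL[q || p]

computed per observed triple, so one training step costs O(|batch| m^2).
Because inducing points come in matched pairs, every required covariance is a
Hadamard product of two m x * kernel matrices instead of a Kronecker product.

All gradients are derived analytically (reverse mode, including the Cholesky
factorization) and validated against finite differences in the test suite;
there is no autodiff framework underneath.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import solve_triangular, cho_solve

from .data import TripleStore
from .kernels import (
    JITTER,
    ArdKernelParams,
    ard_rbf_backward,
    ard_rbf_raw,
    chol_with_jitter,
    cholesky_backward,
)

__all__ = [
    "LatentEmbedding",
    "InducingSet",
    "VariationalState",
    "TrainConfig",
    "MomoGPModel",
    "SingleViewModel",
    "init_model",
    "init_multi_model",
    "elbo",
    "fit",
    "predict_mean_var",
    "log_marginal_exact",
    "optimize_q_analytic",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LatentEmbedding:
    """Trainable lookup table: entity index -> dense latent vector."""

    table: np.ndarray
    entity_kind: str  # "cell" or "feature"

    @property
    def dim(self) -> int:
        return self.table.shape[1]

    @property
    def n_entities(self) -> int:
        return self.table.shape[0]


@dataclass
class InducingSet:
    """Matched inducing pairs: the u-th pair is (cell_indices[u], feature_indices[u]).

    Inducing latents are *tied lookups*: the indices are fixed at init and the
    corresponding rows are re-read from the current embedding tables at every
    step, so inducing points move with the embeddings they index.
    Individual indices may repeat across pairs (only the pairing is matched);
    sampling is without replacement whenever m allows it.
    """

    cell_indices: np.ndarray
    feature_indices: np.ndarray

    def __post_init__(self) -> None:
        self.cell_indices = np.asarray(self.cell_indices, dtype=np.int64)
        self.feature_indices = np.asarray(self.feature_indices, dtype=np.int64)
        if self.cell_indices.shape != self.feature_indices.shape:
            raise ValueError("inducing cell/feature index lists must have equal length")

    @property
    def m(self) -> int:
        return self.cell_indices.size


@dataclass
class VariationalState:
    """Whitened variational distribution q(u) plus the view's noise variance."""

    q_mu: np.ndarray
    q_sqrt: np.ndarray  # lower-triangular, positive diagonal
    noise_variance: float


@dataclass
class TrainConfig:
    """Knobs of the stochastic training loop.

    ``batch_size`` counts observed triples (matrix entries), not cells; the
    paper-scale runs stream minibatches of entries, which is what makes the
    per-epoch cost linear in I*J.
    """

    epochs: int = 200
    batch_size: int = 2048
    learning_rate: float = 1e-2
    seed: int = 0
    view_weights: list[float] | None = None  # optional per-view ELBO weights
    log_every: int = 0  # epochs between stderr log lines; 0 = silent
    #: epochs between closed-form q(u) coordinate updates (Gaussian likelihood
    #: admits the optimal q analytically; interleaving it accelerates
    #: convergence). 0 disables; SGD then owns q entirely.
    analytic_q_every: int = 0


@dataclass
class _ViewSpec:
    """Structural (non-trainable) description of one view."""

    name: str
    n_features: int
    r2: int
    inducing_feature_indices: np.ndarray
    isotropic_features: bool = True


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MomoGPModel:
    """Shared cell embedding + per-view feature embeddings, kernels and q(u).

    Trainable state lives in ``self.params`` (a dict of numpy arrays; scalars
    and ARD weights are stored on log scale to keep them positive).  The class
    covers the single-view model as the one-view special case, so multi-view
    training with one view is bit-identical to single-view training.
    """

    def __init__(self, I: int, r1: int, inducing_cell_indices: np.ndarray,
                 view_specs: list[_ViewSpec], params: dict[str, np.ndarray],
                 seed: int):
        self.I = I
        self.r1 = r1
        self.inducing_cell_indices = np.asarray(inducing_cell_indices, dtype=np.int64)
        self.view_specs = view_specs
        self.params = params
        self.seed = seed
        self.training_log: list[dict] = []

    # -- structural properties ------------------------------------------------

    @property
    def n_views(self) -> int:
        return len(self.view_specs)

    @property
    def m(self) -> int:
        return self.inducing_cell_indices.size

    @property
    def cell_embedding(self) -> LatentEmbedding:
        return LatentEmbedding(self.params["A"], "cell")

    def feature_embedding(self, view: int = 0) -> LatentEmbedding:
        return LatentEmbedding(self.params[f"B{view}"], "feature")

    def inducing(self, view: int = 0) -> InducingSet:
        return InducingSet(self.inducing_cell_indices,
                           self.view_specs[view].inducing_feature_indices)

    def kernel_cells(self, view: int = 0) -> ArdKernelParams:
        return ArdKernelParams(float(np.exp(self.params[f"log_varA{view}"])),
                               np.exp(self.params[f"log_wA{view}"]))

    def kernel_features(self, view: int = 0) -> ArdKernelParams:
        return ArdKernelParams(float(np.exp(self.params[f"log_varB{view}"])),
                               np.exp(self.params[f"log_wB{view}"]))

    def ard_weights(self) -> np.ndarray:
        """Per-view ARD weight vectors on the shared cell kernel, (V, r1)."""
        return np.stack([np.exp(self.params[f"log_wA{v}"]) for v in range(self.n_views)])

    def variational(self, view: int = 0) -> VariationalState:
        return VariationalState(self.params[f"q_mu{view}"].copy(),
                                _q_sqrt(self.params[f"q_raw{view}"]),
                                float(np.exp(self.params[f"log_noise{view}"])))

    def set_variational(self, q_mu: np.ndarray, q_sqrt: np.ndarray, view: int = 0) -> None:
        self.params[f"q_mu{view}"] = np.asarray(q_mu, dtype=float).copy()
        self.params[f"q_raw{view}"] = _q_raw_from_sqrt(np.asarray(q_sqrt, dtype=float))

    def view_index(self, view: int | str | None) -> int:
        if view is None:
            if self.n_views > 1:
                raise ValueError("model has several views; name one")
            return 0
        if isinstance(view, str):
            names = [s.name for s in self.view_specs]
            if view not in names:
                raise ValueError(f"unknown view {view!r}; have {names}")
            return names.index(view)
        if not 0 <= view < self.n_views:
            raise ValueError(f"view index {view} out of range")
        return int(view)

    def copy(self) -> "MomoGPModel":
        m = MomoGPModel(self.I, self.r1, self.inducing_cell_indices.copy(),
                        [
                            _ViewSpec(s.name, s.n_features, s.r2,
                                      s.inducing_feature_indices.copy(), s.isotropic_features)
                            for s in self.view_specs
                        ],
                        {k: np.array(v, dtype=float) for k, v in self.params.items()},
                        self.seed)
        m.training_log = list(self.training_log)
        return m


class SingleViewModel(MomoGPModel):
    """One-view specialization (identical machinery, friendlier accessors)."""


def _q_sqrt(q_raw: np.ndarray) -> np.ndarray:
    """Lower-triangular scale with positive diagonal from unconstrained storage."""
    S = np.tril(q_raw, -1)
    S[np.diag_indices(q_raw.shape[0])] = np.exp(np.diag(q_raw))
    return S


def _q_raw_from_sqrt(S: np.ndarray) -> np.ndarray:
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("q_sqrt must have a positive diagonal")
    raw = np.tril(S, -1)
    raw[np.diag_indices(S.shape[0])] = np.log(d)
    return raw


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

#: standard deviation of the embedding-table initialization
INIT_SCALE = 0.1
#: initial Gaussian observation noise variance per view
INIT_NOISE = 0.1


def _sample_indices(rng: np.random.Generator, size: int, m: int) -> np.ndarray:
    if m <= size:
        return rng.choice(size, size=m, replace=False)
    return rng.choice(size, size=m, replace=True)


def init_multi_model(I: int, feature_counts: list[int], r1: int, r2: int | list[int],
                     m: int, seed: int, view_names: list[str] | None = None,
                     isotropic_features: bool = True) -> MomoGPModel:
    """Random initial model over ``len(feature_counts)`` views of shared cells.

    Embedding tables are N(0, 0.1^2); kernel variances and ARD weights start at
    one; noise variance at 0.1; q(u) at the whitened prior (q_mu = 0,
    q_sqrt = I).  Inducing cell indices are drawn once and shared by all views;
    each view draws its own inducing feature indices.
    """
    if m > I:
        raise ValueError(f"m={m} exceeds the number of cells I={I}")
    V = len(feature_counts)
    r2s = [r2] * V if isinstance(r2, int) else list(r2)
    if len(r2s) != V:
        raise ValueError("r2 list length must match the number of views")
    if view_names is None:
        view_names = [f"view{v}" for v in range(V)]
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {"A": rng.normal(0.0, INIT_SCALE, size=(I, r1))}
    idxA = _sample_indices(rng, I, m)
    specs = []
    for v, (J, r2v) in enumerate(zip(feature_counts, r2s)):
        params[f"B{v}"] = rng.normal(0.0, INIT_SCALE, size=(J, r2v))
        idxB = _sample_indices(rng, J, m)
        specs.append(_ViewSpec(view_names[v], J, r2v, idxB, isotropic_features))
        params[f"log_varA{v}"] = np.zeros(())
        params[f"log_wA{v}"] = np.zeros(r1)
        params[f"log_varB{v}"] = np.zeros(())
        params[f"log_wB{v}"] = np.zeros(r2v)
        params[f"q_mu{v}"] = np.zeros(m)
        params[f"q_raw{v}"] = np.zeros((m, m))
        params[f"log_noise{v}"] = np.full((), np.log(INIT_NOISE))
    return MomoGPModel(I, r1, idxA, specs, params, seed)


def init_model(I: int, J: int, r1: int, r2: int, m: int, seed: int,
               isotropic_features: bool = True) -> SingleViewModel:
    """Random initial single-view model (m <= I and m <= J, both sampled
    without replacement)."""
    if m > I or m > J:
        raise ValueError(f"m={m} must not exceed I={I} or J={J}")
    base = init_multi_model(I, [J], r1, r2, m, seed,
                            isotropic_features=isotropic_features)
    base.__class__ = SingleViewModel
    return base  # type: ignore[return-value]


def set_inducing_pairs(model: MomoGPModel, cell_indices, feature_indices,
                       view: int = 0) -> None:
    """Install an explicit matched inducing-pair set (resets q to the prior).

    Individual indices may repeat; only the pairing is matched.  Useful for
    oracle comparisons where the pairs must cover specific grid points.
    """
    cell_indices = np.asarray(cell_indices, dtype=np.int64)
    feature_indices = np.asarray(feature_indices, dtype=np.int64)
    if cell_indices.shape != feature_indices.shape:
        raise ValueError("cell/feature index lists must have equal length")
    spec = model.view_specs[view]
    if cell_indices.size and (cell_indices.min() < 0 or cell_indices.max() >= model.I):
        raise ValueError("inducing cell index out of range")
    if feature_indices.size and (feature_indices.min() < 0
                                 or feature_indices.max() >= spec.n_features):
        raise ValueError("inducing feature index out of range")
    model.inducing_cell_indices = cell_indices
    spec.inducing_feature_indices = feature_indices
    m = cell_indices.size
    model.params[f"q_mu{view}"] = np.zeros(m)
    model.params[f"q_raw{view}"] = np.zeros((m, m))


def set_full_grid_inducing(model: MomoGPModel, view: int = 0) -> None:
    """Place one inducing pair on every (cell, feature) grid point of a view.

    Oracle helper for tiny problems: with the inducing pairs covering the whole
    grid the sparse bound can match the exact GP.  Repeats individual indices.
    """
    spec = model.view_specs[view]
    I, J = model.I, spec.n_features
    i, j = np.divmod(np.arange(I * J, dtype=np.int64), J)
    model.inducing_cell_indices = i
    spec.inducing_feature_indices = j
    m = I * J
    model.params[f"q_mu{view}"] = np.zeros(m)
    model.params[f"q_raw{view}"] = np.zeros((m, m))


# ---------------------------------------------------------------------------
# ELBO forward + backward for one view
# ---------------------------------------------------------------------------

def _view_elbo_and_grads(params: dict, spec: _ViewSpec, v: int, idxA: np.ndarray,
                         bi: np.ndarray, bj: np.ndarray, by: np.ndarray,
                         total_n: int, want_grads: bool = True):
    """Stochastic ELBO contribution of one view's minibatch, with gradients.

    Returns ``(elbo, grads)``; ``grads`` maps parameter names (including the
    shared "A") to arrays, or is None when ``want_grads`` is False.
    """
    A = params["A"]
    B = params[f"B{v}"]
    varA = float(np.exp(params[f"log_varA{v}"]))
    wA = np.exp(params[f"log_wA{v}"])
    varB = float(np.exp(params[f"log_varB{v}"]))
    wB = np.exp(params[f"log_wB{v}"])
    sigma2 = float(np.exp(params[f"log_noise{v}"]))
    if not sigma2 > 0.0:
        raise FloatingPointError(
            f"view {spec.name}: noise variance underflowed to {sigma2}; "
            "the ELBO is no longer finite")
    q_mu = params[f"q_mu{v}"]
    q_raw = params[f"q_raw{v}"]
    idxB = spec.inducing_feature_indices
    m = idxA.size
    n = bi.size
    scale = total_n / n

    Au, Bu = A[idxA], B[idxB]
    Xa, Xb = A[bi], B[bj]

    KAuu = ard_rbf_raw(Au, Au, varA, wA)
    KBuu = ard_rbf_raw(Bu, Bu, varB, wB)
    jitter = JITTER * varA * varB
    Kuu = KAuu * KBuu + jitter * np.eye(m)
    try:
        L, _ = chol_with_jitter(Kuu, JITTER)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"view {spec.name}: K_uu factorization failed (m={m}, varA={varA:g}, "
            f"varB={varB:g}): {exc}"
        ) from exc

    KAuf = ard_rbf_raw(Au, Xa, varA, wA)
    KBuf = ard_rbf_raw(Bu, Xb, varB, wB)
    Kuf = KAuf * KBuf

    alpha = solve_triangular(L, Kuf, lower=True, check_finite=False)  # (m, n)
    S = _q_sqrt(q_raw)
    mu = alpha.T @ q_mu
    W = S.T @ alpha
    kff = varA * varB
    vq = kff - np.einsum("ut,ut->t", alpha, alpha) + np.einsum("ut,ut->t", W, W)

    resid = by - mu
    sse = float(resid @ resid)
    vsum = float(vq.sum())
    ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * (sse + vsum) / sigma2
    sd = np.diag(S)
    kl = 0.5 * (float(q_mu @ q_mu) + float((S * S).sum()) - m) - float(np.log(sd).sum())
    elbo_val = scale * ll - kl
    if not want_grads:
        return elbo_val, None

    # ---- backward -----------------------------------------------------------
    g_mu = scale * resid / sigma2                       # (n,)
    g_v = -0.5 * scale / sigma2                          # scalar per entry
    g_sigma2 = scale * (-0.5 * n / sigma2 + 0.5 * (sse + vsum) / sigma2 ** 2)

    # d vq / d alpha = -2 alpha
    galpha = q_mu[:, None] * g_mu[None, :] + g_v * (-2.0 * alpha)
    gW = g_v * 2.0 * W
    gS = alpha @ gW.T
    galpha += S @ gW
    g_qmu = alpha @ g_mu - q_mu
    gS -= S
    diag = np.diag_indices(m)
    gS[diag] += 1.0 / sd
    g_qraw = np.tril(gS, -1)
    g_qraw[diag] = gS[diag] * sd

    gvarA = g_v * n * varB  # kff appears once per batch entry
    gvarB = g_v * n * varA

    gKuf = solve_triangular(L.T, galpha, lower=False, check_finite=False)
    gL = -np.tril(gKuf @ alpha.T)
    gKuu = cholesky_backward(L, gL)
    gvarA += JITTER * varB * float(np.trace(gKuu))
    gvarB += JITTER * varA * float(np.trace(gKuu))

    gKAuu = gKuu * KBuu
    gKBuu = gKuu * KAuu
    gKAuf = gKuf * KBuf
    gKBuf = gKuf * KAuf

    gAu_a, gAu_b, gv1, gw1 = ard_rbf_backward(Au, Au, varA, wA, KAuu, gKAuu)
    gAu_c, gXa, gv2, gw2 = ard_rbf_backward(Au, Xa, varA, wA, KAuf, gKAuf)
    gAu = gAu_a + gAu_b + gAu_c
    gvarA += gv1 + gv2
    gwA = gw1 + gw2

    gBu_a, gBu_b, gv3, gw3 = ard_rbf_backward(Bu, Bu, varB, wB, KBuu, gKBuu)
    gBu_c, gXb, gv4, gw4 = ard_rbf_backward(Bu, Xb, varB, wB, KBuf, gKBuf)
    gBu = gBu_a + gBu_b + gBu_c
    gvarB += gv3 + gv4
    gwB = gw3 + gw4

    gA = np.zeros_like(A)
    np.add.at(gA, idxA, gAu)
    np.add.at(gA, bi, gXa)
    gB = np.zeros_like(B)
    np.add.at(gB, idxB, gBu)
    np.add.at(gB, bj, gXb)

    g_log_wB = gwB * wB
    if spec.isotropic_features:  # tied lengthscale: share one gradient across dims
        g_log_wB = np.full_like(g_log_wB, g_log_wB.mean())

    grads = {
        "A": gA,
        f"B{v}": gB,
        f"log_varA{v}": np.asarray(gvarA * varA),
        f"log_wA{v}": gwA * wA,
        f"log_varB{v}": np.asarray(gvarB * varB),
        f"log_wB{v}": g_log_wB,
        f"q_mu{v}": g_qmu,
        f"q_raw{v}": g_qraw,
        f"log_noise{v}": np.asarray(g_sigma2 * sigma2),
    }
    return elbo_val, grads


def elbo(model: MomoGPModel, batch: TripleStore, total_n: int | None = None,
         view: int | str | None = None) -> float:
    """Stochastic evidence lower bound of one view's (mini)batch.

    ``total_n`` is the full triple count of the view; defaults to the batch
    size (i.e. full-batch).  The returned value lower-bounds the exact log
    marginal likelihood when the batch is the full store.
    """
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    v = model.view_index(view)
    total = int(total_n) if total_n is not None else len(batch)
    val, _ = _view_elbo_and_grads(model.params, model.view_specs[v], v,
                                  model.inducing_cell_indices,
                                  batch.i, batch.j, batch.y, total,
                                  want_grads=False)
    return float(val)


def elbo_and_grads(model: MomoGPModel, batch: TripleStore, total_n: int | None = None,
                   view: int | str | None = None):
    """ELBO plus analytic gradients w.r.t. every trainable array (test hook)."""
    v = model.view_index(view)
    total = int(total_n) if total_n is not None else len(batch)
    return _view_elbo_and_grads(model.params, model.view_specs[v], v,
                                model.inducing_cell_indices,
                                batch.i, batch.j, batch.y, total)


# ---------------------------------------------------------------------------
# training loop (Adam)
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        # gradient *ascent* on the ELBO
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] + self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def fit(model: MomoGPModel, store: TripleStore, config: TrainConfig | None = None
        ) -> MomoGPModel:
    """Train a single-view model by stochastic gradient ascent on the ELBO."""
    return fit_views(model, [store], config)


def fit_views(model: MomoGPModel, stores: list[TripleStore],
              config: TrainConfig | None = None) -> MomoGPModel:
    """Train on one store per view, maximizing the summed per-view ELBO.

    Every epoch each view's triples are reshuffled and cut into minibatches;
    one optimizer step consumes one minibatch from *each* view (shorter views
    cycle), so the shared cell embedding receives signal from all modalities
    at every step.  Per-epoch mean ELBO (already scaled to full-data) is
    recorded in ``model.training_log``.
    """
    config = config or TrainConfig()
    if len(stores) != model.n_views:
        raise ValueError(f"model has {model.n_views} views but got {len(stores)} stores")
    I0 = stores[0].n_cells
    for s in stores:
        if s.n_cells != I0:
            raise ValueError("all views must share the same cells "
                             f"({s.view_name}: {s.n_cells} != {I0})")
    if I0 != model.I:
        raise ValueError(f"store has {I0} cells but model was built for {model.I}")
    for s, spec in zip(stores, model.view_specs):
        if s.n_features != spec.n_features:
            raise ValueError(f"view {spec.name}: store has {s.n_features} features, "
                             f"model expects {spec.n_features}")

    weights = config.view_weights or [1.0] * model.n_views
    model = model.copy()
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    totals = [len(s) for s in stores]
    bs = config.batch_size
    nbatches = [max(1, int(np.ceil(t / bs))) for t in totals]
    steps_per_epoch = max(nbatches)

    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        perms = [rng.permutation(t) for t in totals]
        epoch_elbo = np.zeros(model.n_views)
        counts = np.zeros(model.n_views)
        for step in range(steps_per_epoch):
            grads_sum: dict[str, np.ndarray] = {}
            for v, (s, perm) in enumerate(zip(stores, perms)):
                b = step % nbatches[v]
                sel = perm[b * bs:(b + 1) * bs]
                val, grads = _view_elbo_and_grads(
                    model.params, model.view_specs[v], v,
                    model.inducing_cell_indices,
                    s.i[sel], s.j[sel], s.y[sel], totals[v])
                if not np.isfinite(val):
                    raise FloatingPointError(
                        f"non-finite ELBO at epoch {epoch}, view {v} "
                        f"(noise={np.exp(model.params[f'log_noise{v}']):g}); aborting")
                epoch_elbo[v] += val
                counts[v] += 1
                wv = weights[v]
                for k, g in grads.items():
                    if k in grads_sum:
                        grads_sum[k] += wv * g
                    else:
                        grads_sum[k] = wv * g if wv != 1.0 else g.copy()
            opt.step(model.params, grads_sum)
        if config.analytic_q_every and (epoch + 1) % config.analytic_q_every == 0:
            for v, s in enumerate(stores):
                updated = optimize_q_analytic(model, s, view=v)
                model.params[f"q_mu{v}"] = updated.params[f"q_mu{v}"]
                model.params[f"q_raw{v}"] = updated.params[f"q_raw{v}"]
                opt.m[f"q_mu{v}"][:] = 0.0
                opt.v[f"q_mu{v}"][:] = 0.0
                opt.m[f"q_raw{v}"][:] = 0.0
                opt.v[f"q_raw{v}"][:] = 0.0
        per_view = epoch_elbo / counts
        model.training_log.append({
            "epoch": epoch,
            "elbo": float(per_view.sum()),
            "elbo_per_view": per_view.tolist(),
            "seconds": time.perf_counter() - t0,
        })
        if config.log_every and (epoch + 1) % config.log_every == 0:
            import sys
            print(f"[momogp] epoch {epoch + 1}/{config.epochs} "
                  f"elbo={per_view.sum():.2f}", file=sys.stderr)
    return model


def fit_multi(stores: list[TripleStore], config: TrainConfig | None = None, *,
              r1: int = 2, r2: int | list[int] = 2, m: int = 64,
              view_names: list[str] | None = None,
              model: MomoGPModel | None = None) -> MomoGPModel:
    """Initialize (unless given) and train a multi-view model on shared cells."""
    config = config or TrainConfig()
    if model is None:
        if view_names is None:
            view_names = [s.view_name for s in stores]
        model = init_multi_model(stores[0].n_cells, [s.n_features for s in stores],
                                 r1, r2, m, config.seed, view_names)
    return fit_views(model, stores, config)


# ---------------------------------------------------------------------------
# posterior prediction
# ---------------------------------------------------------------------------

def _posterior_factors(model: MomoGPModel, v: int):
    """(L, c, S) with c = L^{-T} q_mu, so mu(x) = K_uf(x)^T c."""
    spec = model.view_specs[v]
    A, B = model.params["A"], model.params[f"B{v}"]
    pa, pb = model.kernel_cells(v), model.kernel_features(v)
    Au, Bu = A[model.inducing_cell_indices], B[spec.inducing_feature_indices]
    KAuu = ard_rbf_raw(Au, Au, pa.variance, pa.ard_weights)
    KBuu = ard_rbf_raw(Bu, Bu, pb.variance, pb.ard_weights)
    Kuu = KAuu * KBuu + JITTER * pa.variance * pb.variance * np.eye(model.m)
    L, _ = chol_with_jitter(Kuu, JITTER)
    c = solve_triangular(L.T, model.params[f"q_mu{v}"], lower=False, check_finite=False)
    S = _q_sqrt(model.params[f"q_raw{v}"])
    return L, c, S, Au, Bu, pa, pb


def predict_mean_var(model: MomoGPModel, cells, features,
                     view: int | str | None = None):
    """Posterior mean and marginal variance of f over a cell x feature grid.

    Returns arrays of shape (len(cells), len(features)); variance excludes the
    observation noise.
    """
    v = model.view_index(view)
    cells = np.asarray(cells, dtype=np.int64)
    features = np.asarray(features, dtype=np.int64)
    if cells.size and (cells.min() < 0 or cells.max() >= model.I):
        raise ValueError("cell index out of range")
    J = model.view_specs[v].n_features
    if features.size and (features.min() < 0 or features.max() >= J):
        raise ValueError("feature index out of range")

    L, c, S, Au, Bu, pa, pb = _posterior_factors(model, v)
    A, B = model.params["A"], model.params[f"B{v}"]
    KAx = ard_rbf_raw(Au, A[cells], pa.variance, pa.ard_weights)   # (m, nc)
    KBx = ard_rbf_raw(Bu, B[features], pb.variance, pb.ard_weights)  # (m, nf)
    mean = np.einsum("u,ui,uj->ij", c, KAx, KBx)
    kff = pa.variance * pb.variance

    nc, nf = cells.size, features.size
    var = np.empty((nc, nf))
    for i in range(nc):
        Kuf = KAx[:, i][:, None] * KBx  # (m, nf)
        alpha = solve_triangular(L, Kuf, lower=True, check_finite=False)
        W = S.T @ alpha
        var[i] = kff - np.einsum("uj,uj->j", alpha, alpha) + np.einsum("uj,uj->j", W, W)
    return mean, np.maximum(var, 0.0)


def posterior_mean_at_latent(model: MomoGPModel, a: np.ndarray, features,
                             view: int | str | None = None) -> np.ndarray:
    """Posterior mean of f at an arbitrary cell-latent position ``a``.

    Used by the relevance machinery (and its finite-difference oracle), which
    differentiates the mean with respect to the cell coordinate.
    """
    v = model.view_index(view)
    a = np.asarray(a, dtype=float).reshape(1, -1)
    features = np.asarray(features, dtype=np.int64)
    L, c, S, Au, Bu, pa, pb = _posterior_factors(model, v)
    B = model.params[f"B{v}"]
    ka = ard_rbf_raw(Au, a, pa.variance, pa.ard_weights)[:, 0]  # (m,)
    KBx = ard_rbf_raw(Bu, B[features], pb.variance, pb.ard_weights)  # (m, nf)
    return (c * ka) @ KBx


# ---------------------------------------------------------------------------
# exact-GP oracle helpers (small problems only)
# ---------------------------------------------------------------------------

def log_marginal_exact(model: MomoGPModel, store: TripleStore,
                       view: int | str | None = None, guard: int = 10_000) -> float:
    """Exact GP log marginal likelihood of a view's triples (O(n^3) oracle).

    Builds the dense coregionalization covariance over the observed triples
    (for a full grid this is the Kronecker kernel) plus noise, and evaluates
    the Gaussian log density of y.  Refuses above ``guard`` triples.
    """
    v = model.view_index(view)
    n = len(store)
    if n > guard:
        raise ValueError(f"{n} triples exceed the exact-oracle guard {guard}")
    A, B = model.params["A"], model.params[f"B{v}"]
    pa, pb = model.kernel_cells(v), model.kernel_features(v)
    Xa, Xb = A[store.i], B[store.j]
    K = (ard_rbf_raw(Xa, Xa, pa.variance, pa.ard_weights)
         * ard_rbf_raw(Xb, Xb, pb.variance, pb.ard_weights))
    sigma2 = float(np.exp(model.params[f"log_noise{v}"]))
    Ky = K + sigma2 * np.eye(n)
    L, _ = chol_with_jitter(Ky, JITTER)
    alpha = solve_triangular(L, store.y, lower=True, check_finite=False)
    return float(-0.5 * alpha @ alpha - np.log(np.diag(L)).sum()
                 - 0.5 * n * np.log(2.0 * np.pi))


def optimize_q_analytic(model: MomoGPModel, store: TripleStore,
                        view: int | str | None = None) -> MomoGPModel:
    """Set q(u) to its analytically optimal value for fixed kernels/embeddings.

    For a Gaussian likelihood the optimal whitened q(u) is available in closed
    form; with it the stochastic bound equals the collapsed (Titsias) bound.
    Returns a modified copy.
    """
    v = model.view_index(view)
    model = model.copy()
    spec = model.view_specs[v]
    A, B = model.params["A"], model.params[f"B{v}"]
    pa, pb = model.kernel_cells(v), model.kernel_features(v)
    sigma2 = float(np.exp(model.params[f"log_noise{v}"]))
    Au, Bu = A[model.inducing_cell_indices], B[spec.inducing_feature_indices]
    KAuu = ard_rbf_raw(Au, Au, pa.variance, pa.ard_weights)
    KBuu = ard_rbf_raw(Bu, Bu, pb.variance, pb.ard_weights)
    Kuu = KAuu * KBuu + JITTER * pa.variance * pb.variance * np.eye(model.m)
    L, _ = chol_with_jitter(Kuu, JITTER)
    Kuf = (ard_rbf_raw(Au, A[store.i], pa.variance, pa.ard_weights)
           * ard_rbf_raw(Bu, B[store.j], pb.variance, pb.ard_weights))
    alpha = solve_triangular(L, Kuf, lower=True, check_finite=False)
    P = np.eye(model.m) + (alpha @ alpha.T) / sigma2
    Lp, _ = chol_with_jitter(P, 1e-12)
    S_opt = cho_solve((Lp, True), np.eye(model.m), check_finite=False)
    S_opt = 0.5 * (S_opt + S_opt.T)
    q_mu = cho_solve((Lp, True), alpha @ store.y, check_finite=False) / sigma2
    q_sqrt = np.linalg.cholesky(S_opt + 1e-12 * np.eye(model.m))
    model.set_variational(q_mu, q_sqrt, v)
    return model


# ---------------------------------------------------------------------------
# checkpoints (TSV matrices + one JSON of scalars)
# ---------------------------------------------------------------------------

def _write_embedding_tsv(path: str, table: np.ndarray, ids: list[str] | None) -> None:
    dim = table.shape[1]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"dim{r}" for r in range(dim)) + "\n")
        for k, row in enumerate(table):
            name = ids[k] if ids else str(k)
            fh.write(name + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def _read_embedding_tsv(path: str):
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def save_model(model: MomoGPModel, directory: str,
               cell_ids: list[str] | None = None,
               feature_ids: list[list[str]] | None = None,
               extra: dict | None = None) -> None:
    """Write a checkpoint: TSV embeddings per entity set + params.json scalars."""
    os.makedirs(directory, exist_ok=True)
    _write_embedding_tsv(os.path.join(directory, "cell_embedding.tsv"),
                         model.params["A"], cell_ids)
    meta: dict = {
        "I": model.I, "r1": model.r1, "m": model.m, "seed": model.seed,
        "inducing_cell_indices": model.inducing_cell_indices.tolist(),
        "views": [],
    }
    if extra:
        meta["config"] = extra
    for v, spec in enumerate(model.view_specs):
        vdir = os.path.join(directory, f"view_{spec.name}")
        os.makedirs(vdir, exist_ok=True)
        ids = feature_ids[v] if feature_ids else None
        _write_embedding_tsv(os.path.join(vdir, "feature_embedding.tsv"),
                             model.params[f"B{v}"], ids)
        np.savetxt(os.path.join(vdir, "q_mu.tsv"), model.params[f"q_mu{v}"],
                   delimiter="\t")
        np.savetxt(os.path.join(vdir, "q_raw.tsv"), model.params[f"q_raw{v}"],
                   delimiter="\t")
        meta["views"].append({
            "name": spec.name,
            "n_features": spec.n_features,
            "r2": spec.r2,
            "isotropic_features": spec.isotropic_features,
            "inducing_feature_indices": spec.inducing_feature_indices.tolist(),
            "log_varA": float(model.params[f"log_varA{v}"]),
            "log_wA": np.asarray(model.params[f"log_wA{v}"]).tolist(),
            "log_varB": float(model.params[f"log_varB{v}"]),
            "log_wB": np.asarray(model.params[f"log_wB{v}"]).tolist(),
            "log_noise": float(model.params[f"log_noise{v}"]),
        })
    with open(os.path.join(directory, "params.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(directory: str) -> MomoGPModel:
    with open(os.path.join(directory, "params.json")) as fh:
        meta = json.load(fh)
    A, _ = _read_embedding_tsv(os.path.join(directory, "cell_embedding.tsv"))
    params: dict[str, np.ndarray] = {"A": A}
    specs = []
    for v, vm in enumerate(meta["views"]):
        vdir = os.path.join(directory, f"view_{vm['name']}")
        B, _ = _read_embedding_tsv(os.path.join(vdir, "feature_embedding.tsv"))
        params[f"B{v}"] = B
        params[f"q_mu{v}"] = np.atleast_1d(
            np.loadtxt(os.path.join(vdir, "q_mu.tsv"), delimiter="\t"))
        params[f"q_raw{v}"] = np.atleast_2d(
            np.loadtxt(os.path.join(vdir, "q_raw.tsv"), delimiter="\t"))
        params[f"log_varA{v}"] = np.asarray(vm["log_varA"])
        params[f"log_wA{v}"] = np.asarray(vm["log_wA"], dtype=float)
        params[f"log_varB{v}"] = np.asarray(vm["log_varB"])
        params[f"log_wB{v}"] = np.asarray(vm["log_wB"], dtype=float)
        params[f"log_noise{v}"] = np.asarray(vm["log_noise"])
        specs.append(_ViewSpec(vm["name"], vm["n_features"], vm["r2"],
                               np.asarray(vm["inducing_feature_indices"], dtype=np.int64),
                               vm.get("isotropic_features", True)))
    return MomoGPModel(meta["I"], meta["r1"],
                       np.asarray(meta["inducing_cell_indices"], dtype=np.int64),
                       specs, params, meta.get("seed", 0))
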