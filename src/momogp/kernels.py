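"""ARD-RBF kernels and the coregionalization kernel over (cell, feature) pairs.

The model places one RBF kernel with automatic relevance determination (ARD)
on the cell latent space and one on each feature latent space.  The prior
covariance over the vectorized cell x feature grid is the Kronecker product of
the two kernel matrices ("coregionalization kernel").  With matched inducing
pairs -- the u-th inducing point is a *pair* (a_u, b_u) of a cell latent and a
feature latent -- every cross-covariance the sparse bound needs collapses to an
elementwise (Hadamard) product of the two small kernel matrices, which is what
makes training linear in the number of observed entries.

Vectorization order is cell-major throughout: grid entry t = i * J + j, the
row ordering of ``np.kron(KA, KB)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Relative jitter added to square kernel diagonals before factorization.
JITTER = 1e-6

#: Guard on I*J for materializing the full Kronecker kernel (oracle-only path).
KRON_GUARD = 10_000


@dataclass
class ArdKernelParams:
    """Amplitude and per-dimension ARD weights of an RBF kernel.

    ``k(x, x') = variance * exp(-0.5 * sum_r ard_weights[r] * (x_r - x'_r)^2)``

    A weight of zero removes a latent dimension's influence entirely; large
    weights make the kernel sensitive to that dimension (ARD weights are
    inverse squared lengthscales).
    """

    variance: float
    ard_weights: np.ndarray

    def __post_init__(self) -> None:
        self.ard_weights = np.asarray(self.ard_weights, dtype=float)
        if self.ard_weights.ndim != 1:
            raise ValueError("ard_weights must be a 1-D vector")
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")
        if np.any(self.ard_weights < 0):
            raise ValueError("ard_weights must be >= 0")

    @property
    def dim(self) -> int:
        return self.ard_weights.shape[0]


@dataclass
class CovMatrix:
    """A covariance matrix tagged with the entities its axes index."""

    values: np.ndarray
    row_entities: str = ""
    col_entities: str = ""

    @property
    def shape(self):
        return self.values.shape


def _check_dims(X: np.ndarray, params: ArdKernelParams, name: str) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.dim:
        raise ValueError(
            f"{name} has latent dimension {X.shape[1]} but kernel expects {params.dim}"
        )
    return X


def ard_rbf(X, X2, params: ArdKernelParams) -> CovMatrix:
    """ARD-RBF covariance between two sets of latent points.

    Parameters
    ----------
    X, X2
        Arrays of shape (n, r) and (n2, r).  Pass the same array twice for a
        square kernel matrix.
    params
        Kernel amplitude and per-dimension weights (length r).
    """
    X = _check_dims(X, params, "X")
    X2 = _check_dims(X2, params, "X2")
    K = params.variance * np.exp(-0.5 * _sqdist_weighted(X, X2, params.ard_weights))
    return CovMatrix(K)


def _sqdist_weighted(X: np.ndarray, X2: np.ndarray, w: np.ndarray) -> np.ndarray:
    """sum_r w_r (x_ir - x2_jr)^2 for all pairs, computed stably."""
    Xw = X * w
    d = (Xw * X).sum(1)[:, None] + (X2 * w * X2).sum(1)[None, :] - 2.0 * Xw @ X2.T
    return np.maximum(d, 0.0)


def ard_rbf_raw(X: np.ndarray, X2: np.ndarray, variance: float, w: np.ndarray) -> np.ndarray:
    """Plain-array fast path used by the training loop."""
    return variance * np.exp(-0.5 * _sqdist_weighted(X, X2, w))


def ard_rbf_backward(
    X: np.ndarray,
    X2: np.ndarray,
    variance: float,
    w: np.ndarray,
    K: np.ndarray,
    Kbar: np.ndarray,
):
    """Reverse-mode gradients of an ARD-RBF kernel matrix.

    Given the forward kernel ``K = ard_rbf_raw(X, X2, variance, w)`` and the
    upstream gradient ``Kbar = d(objective)/dK``, returns
    ``(gX, gX2, gvariance, gw)``.  When X and X2 are the *same* array the
    caller must sum gX and gX2.
    """
    E = Kbar * K  # shared elementwise factor
    gvar = float(E.sum() / variance) if variance > 0 else 0.0
    rs = E.sum(axis=1)  # (n,)
    cs = E.sum(axis=0)  # (n2,)
    EX2 = E @ X2  # (n, r)
    ETX = E.T @ X  # (n2, r)
    gX = -w * (rs[:, None] * X - EX2)
    gX2 = -w * (cs[:, None] * X2 - ETX)
    gw = -0.5 * (
        rs @ (X * X) - 2.0 * np.einsum("ir,ir->r", X, EX2) + cs @ (X2 * X2)
    )
    return gX, gX2, gvar, gw


def coreg_kernel_full(KA: CovMatrix | np.ndarray, KB: CovMatrix | np.ndarray,
                      guard: int = KRON_GUARD) -> CovMatrix:
    """Full Kronecker coregionalization kernel (oracle path, small grids only).

    Row t = i * J + j of the result indexes grid entry (cell i, feature j),
    matching the triple-store vectorization order.
    """
    A = KA.values if isinstance(KA, CovMatrix) else np.asarray(KA, dtype=float)
    B = KB.values if isinstance(KB, CovMatrix) else np.asarray(KB, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("KA must be square")
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("KB must be square")
    n = A.shape[0] * B.shape[0]
    if n > guard:
        raise ValueError(
            f"full coregionalization kernel would be {n}x{n} (> guard {guard}); "
            "this path is an exact-oracle path for small grids only"
        )
    return CovMatrix(np.kron(A, B), "cell x feature grid", "cell x feature grid")


def coreg_cross_cov(
    cell_latents_at_triples: np.ndarray,
    feat_latents_at_triples: np.ndarray,
    Au: np.ndarray,
    Bu: np.ndarray,
    paramsA: ArdKernelParams,
    paramsB: ArdKernelParams,
) -> CovMatrix:
    """Cross-covariance K_uf between matched inducing pairs and observed triples.

    ``K_uf[u, t] = k_A(a_u, a_{i(t)}) * k_B(b_u, b_{j(t)})`` -- the Hadamard
    replacement of the Kronecker product, valid because inducing points come in
    matched (cell, feature) pairs.
    """
    Au = np.atleast_2d(np.asarray(Au, dtype=float))
    Bu = np.atleast_2d(np.asarray(Bu, dtype=float))
    if Au.shape[0] != Bu.shape[0]:
        raise ValueError(
            f"matched inducing pairs require equal row counts, got {Au.shape[0]} and {Bu.shape[0]}"
        )
    KufA = ard_rbf(Au, cell_latents_at_triples, paramsA).values
    KufB = ard_rbf(Bu, feat_latents_at_triples, paramsB).values
    return CovMatrix(KufA * KufB, "inducing pairs", "triples")


def coreg_kuu(Au, Bu, paramsA: ArdKernelParams, paramsB: ArdKernelParams,
              jitter: float | None = None) -> CovMatrix:
    """Inducing-vs-inducing covariance K_uu = K_A(Au,Au) o K_B(Bu,Bu) (+ jitter)."""
    Au = np.atleast_2d(np.asarray(Au, dtype=float))
    Bu = np.atleast_2d(np.asarray(Bu, dtype=float))
    if Au.shape[0] != Bu.shape[0]:
        raise ValueError("matched inducing pairs require equal row counts")
    K = ard_rbf(Au, Au, paramsA).values * ard_rbf(Bu, Bu, paramsB).values
    if jitter is None:
        jitter = JITTER * paramsA.variance * paramsB.variance
    K = K + jitter * np.eye(K.shape[0])
    return CovMatrix(K, "inducing pairs", "inducing pairs")


def chol_with_jitter(K: np.ndarray, base_jitter: float, max_jitter: float = 1e-4):
    """Cholesky with jitter escalation base -> 1e-4 (relative to mean diagonal).

    Returns (L, jitter_used).  Raises ``np.linalg.LinAlgError`` with diagnostics
    if the matrix stays indefinite at the maximum jitter.
    """
    scale = float(np.mean(np.diag(K))) or 1.0
    jit = base_jitter
    while True:
        try:
            return np.linalg.cholesky(K + (jit - base_jitter) * scale * np.eye(K.shape[0])), jit
        except np.linalg.LinAlgError:
            if jit >= max_jitter:
                raise np.linalg.LinAlgError(
                    f"Cholesky failed at jitter {jit:g}; min diag {np.min(np.diag(K)):g}, "
                    f"matrix size {K.shape[0]}"
                )
            jit = min(jit * 10.0, max_jitter)


def cholesky_backward(L: np.ndarray, Lbar: np.ndarray) -> np.ndarray:
    """Reverse-mode derivative through K = L L^T (L lower-triangular).

    Given the gradient ``Lbar`` w.r.t. L, returns the gradient w.r.t. the
    (symmetric) input matrix K.
    """
    m = L.shape[0]
    P = L.T @ np.tril(Lbar)
    # take the lower triangle, halving the diagonal
    Phi = np.tril(P)
    Phi[np.diag_indices(m)] *= 0.5
    iL = np.linalg.inv(L)
    Kbar = iL.T @ Phi @ iL
    return 0.5 * (Kbar + Kbar.T)
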