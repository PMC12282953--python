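"""Metagenes, relevance maps, and linking feature groups to cell groups.

The feature embedding clusters naturally into "metagenes" (groups of features
with nearby latent coordinates, hence correlated predicted expression).  A
*relevance map* scores, for every cell, how strongly a feature set's predicted
expression responds to movement of that cell's latent coordinate: the score is
the gradient norm ||d mu_ij / d a_i||_2 of the GP posterior mean with respect
to the cell latent, averaged over the features of the set.  Regions of the
cell embedding where a metagene's relevance is high are the cells that
metagene characterizes -- a clustering-free alternative to per-cluster
differential expression.

Raw gradient norms carry a nonzero floor everywhere (the posterior mean
wiggles slightly even far from a feature set's active region), so scores are
background-subtracted before scaling: the per-set median over evaluated
cells is taken as the typical background level, scores below it clip to
zero, and the result is scaled so the peak is 100.  The linking threshold
tau then reads as "at least tau% of the way from typical background to peak
relevance" (tau = 30 by default); a degenerate all-equal relevance column
becomes all zero and links no cells at any tau > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.mixture import GaussianMixture

from .data import CellLabels
from .kernels import ard_rbf_raw
from .model import LatentEmbedding, MomoGPModel, _posterior_factors

__all__ = [
    "MetageneAssignment",
    "RelevanceMap",
    "cluster_features",
    "feature_relevance",
    "relevance_map",
    "link_metagene_to_cells",
    "majority_celltype",
    "metagene_enrichment",
]


@dataclass
class MetageneAssignment:
    """feature index -> metagene id (0..G-1), plus method metadata."""

    assignment: np.ndarray
    n_metagenes: int
    method: dict = field(default_factory=dict)

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == g)

    def to_frame(self, feature_ids: list[str] | None = None) -> pd.DataFrame:
        idx = feature_ids if feature_ids is not None else np.arange(self.assignment.size)
        return pd.DataFrame({"feature": idx, "metagene": self.assignment})


@dataclass
class RelevanceMap:
    """cells x metagenes relevance scores, background-subtracted and scaled
    to [0, 100] per column."""

    scores: np.ndarray
    cell_indices: np.ndarray
    metagene_ids: list[int]
    tau: float = 30.0

    def column(self, metagene: int) -> np.ndarray:
        if metagene not in self.metagene_ids:
            raise ValueError(f"unknown metagene id {metagene}")
        return self.scores[:, self.metagene_ids.index(metagene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_indices,
                            columns=[f"metagene_{g}" for g in self.metagene_ids])


# ---------------------------------------------------------------------------
# metagenes
# ---------------------------------------------------------------------------

def cluster_features(feature_embedding: LatentEmbedding | np.ndarray,
                     G: int | None = None, seed: int = 0,
                     bic_range: range = range(2, 16)) -> MetageneAssignment:
    """Gaussian-mixture clustering of the feature latents into G metagenes.

    With ``G=None`` the component count is chosen by BIC over ``bic_range``
    (capped at the number of features).
    """
    X = feature_embedding.table if isinstance(feature_embedding, LatentEmbedding) \
        else np.asarray(feature_embedding, dtype=float)
    J = X.shape[0]
    if G is not None:
        if not 1 <= G <= J:
            raise ValueError(f"G={G} must be in [1, {J}]")
        gmm = GaussianMixture(G, covariance_type="full", random_state=seed,
                              n_init=5).fit(X)
        return MetageneAssignment(gmm.predict(X), G,
                                  {"algorithm": "gmm", "G": G, "seed": seed})
    best = None
    for g in bic_range:
        if g > J:
            break
        gmm = GaussianMixture(g, covariance_type="full", random_state=seed,
                              n_init=5).fit(X)
        bic = gmm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, g, gmm)
    bic, g, gmm = best
    return MetageneAssignment(gmm.predict(X), g,
                              {"algorithm": "gmm", "G": g, "seed": seed,
                               "selected_by": "bic"})


# ---------------------------------------------------------------------------
# relevance
# ---------------------------------------------------------------------------

def _relevance_raw(model: MomoGPModel, feature_set: np.ndarray,
                   cell_latents: np.ndarray, v: int) -> np.ndarray:
    """Mean over the feature set of ||d mu_ij / d a_i|| at each cell latent.

    Analytic gradient: mu_j(a) = sum_u c_u k_A(a, a_u) k_B(b_j, b_u), so
    d mu_j / d a = sum_u c_u k_B[j,u] k_A(a, a_u) * w .* (a_u - a).
    """
    L, c, S, Au, Bu, pa, pb = _posterior_factors(model, v)
    B = model.params[f"B{v}"]
    KB = ard_rbf_raw(Bu, B[feature_set], pb.variance, pb.ard_weights)  # (m, nf)
    w = pa.ard_weights
    out = np.empty(cell_latents.shape[0])
    for t, a in enumerate(cell_latents):
        ka = ard_rbf_raw(Au, a[None, :], pa.variance, w)[:, 0]         # (m,)
        D = w[None, :] * (Au - a[None, :])                             # (m, r1)
        grads = KB.T @ ((c * ka)[:, None] * D)                         # (nf, r1)
        out[t] = np.mean(np.linalg.norm(grads, axis=1))
    return out


def feature_relevance(model: MomoGPModel, feature_set, eval_cells,
                      view: int | str | None = None, scale: bool = True) -> np.ndarray:
    """Per-cell relevance of a feature set.

    With ``scale=True`` (default) scores are background-subtracted at the
    per-set median and scaled so the maximum over ``eval_cells`` is 100;
    ``scale=False`` returns raw gradient norms.
    """
    v = model.view_index(view)
    feature_set = np.asarray(feature_set, dtype=np.int64)
    if feature_set.size == 0:
        raise ValueError("feature_set must be non-empty")
    J = model.view_specs[v].n_features
    if feature_set.min() < 0 or feature_set.max() >= J:
        raise ValueError("feature index out of range")
    eval_cells = np.asarray(eval_cells, dtype=np.int64)
    A = model.params["A"]
    raw = _relevance_raw(model, feature_set, A[eval_cells], v)
    if scale:
        raw = np.clip(raw - np.median(raw), 0.0, None)
        peak = raw.max()
        if peak > 0:
            raw = raw * (100.0 / peak)
    return raw


def relevance_map(model: MomoGPModel, metagenes: MetageneAssignment,
                  eval_cells=None, view: int | str | None = None,
                  tau: float = 30.0) -> RelevanceMap:
    """Relevance of every metagene at every evaluated cell."""
    v = model.view_index(view)
    if eval_cells is None:
        eval_cells = np.arange(model.I)
    eval_cells = np.asarray(eval_cells, dtype=np.int64)
    ids = sorted(set(metagenes.assignment.tolist()))
    scores = np.column_stack([
        feature_relevance(model, metagenes.members(g), eval_cells, view=v)
        for g in ids
    ])
    return RelevanceMap(scores, eval_cells, ids, tau)


def link_metagene_to_cells(relevance: RelevanceMap, metagene: int,
                           tau: float | None = None) -> np.ndarray:
    """Cells whose relevance for the metagene exceeds tau (percent of peak)."""
    if tau is None:
        tau = relevance.tau
    if not 0.0 <= tau <= 100.0:
        raise ValueError("tau must be in [0, 100]")
    col = relevance.column(metagene)
    return relevance.cell_indices[col > tau]


# ---------------------------------------------------------------------------
# cell-type summaries
# ---------------------------------------------------------------------------

def majority_celltype(cells, labels: CellLabels | np.ndarray,
                      cell_ids: list[str] | None = None):
    """Modal cell type of a cell set and its percentage (ties lexicographic).

    ``labels`` may be a :class:`CellLabels` (then ``cell_ids`` maps indices to
    barcodes) or a plain array of per-cell label strings indexed directly.
    """
    cells = np.asarray(cells)
    if cells.size == 0:
        raise ValueError("empty cell set")
    if isinstance(labels, CellLabels):
        if cell_ids is None:
            raise ValueError("cell_ids needed to look up CellLabels by index")
        lab = np.array([labels.mapping[cell_ids[i]] for i in cells])
    else:
        lab = np.asarray(labels)[cells]
    types, counts = np.unique(lab, return_counts=True)  # np.unique sorts -> ties lexicographic
    best = types[np.argmax(counts)]
    return str(best), float(100.0 * counts.max() / lab.size)


def metagene_enrichment(metagene_features, marker_sets: dict[str, set],
                        universe) -> pd.DataFrame:
    """Over-representation of each cell type's markers in a metagene.

    For each cell type: coverage = percentage of the metagene's marker-labeled
    features that carry this type's label, and a hypergeometric upper-tail
    p-value for drawing at least the observed overlap when sampling
    ``len(metagene)`` features from the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty feature universe")
    metagene_features = set(metagene_features) & universe
    labeled = metagene_features & set().union(*marker_sets.values()) if marker_sets else set()
    rows = []
    N = len(universe)
    n_draw = len(metagene_features)
    for cell_type, markers in sorted(marker_sets.items()):
        markers = set(markers)
        if not markers <= universe:
            raise ValueError(f"markers of {cell_type!r} not all in the universe")
        k = len(metagene_features & markers)
        coverage = 100.0 * k / len(labeled) if labeled else 0.0
        # P(X >= k) for X ~ Hypergeom(N, |markers|, n_draw)
        pval = float(hypergeom.sf(k - 1, N, len(markers), n_draw)) if k > 0 else 1.0
        rows.append({"cell_type": cell_type, "overlap": k,
                     "coverage_pct": coverage, "p_value": min(pval, 1.0)})
    return pd.DataFrame(rows)
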