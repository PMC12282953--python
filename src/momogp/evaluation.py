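"""Embedding quality metrics: unsupervised clustering, ACC and ARI.

ACC clusters the embedding with k set to the number of cell types, assigns
each cluster the most frequent true label among its members (independently
per cluster -- two clusters may share a predicted label), and reports the
percentage of entities whose predicted label matches their true label.  ARI
is the chance-adjusted Rand index between the unsupervised clustering and the
label partition.  On imbalanced labelings (e.g. a dominant "unknown" class)
ACC can be high while ARI stays low, which is why both are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

__all__ = ["ClusteringResult", "MetricReport", "cluster_embedding",
           "clustering_accuracy", "adjusted_rand_index", "evaluate_embedding"]


@dataclass
class ClusteringResult:
    assignment: np.ndarray
    k: int
    algorithm: str
    seed: int


@dataclass
class MetricReport:
    acc: float
    ari: float
    k: int
    algorithm: str
    seed: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"acc": self.acc, "ari": self.ari, "k": self.k,
                       "algorithm": self.algorithm, "seed": self.seed}, fh, indent=1)


def cluster_embedding(embedding: np.ndarray, k: int, algorithm: str = "gmm",
                      seed: int = 0, n_init: int = 5) -> ClusteringResult:
    """Cluster embedded entities with a GMM (full covariances) or k-means."""
    X = np.asarray(embedding, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of entities {X.shape[0]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if algorithm == "gmm":
        modelc = GaussianMixture(k, covariance_type="full", random_state=seed,
                                 n_init=n_init)
        labels = modelc.fit(X).predict(X)
    elif algorithm == "kmeans":
        labels = KMeans(k, random_state=seed, n_init=n_init).fit_predict(X)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return ClusteringResult(labels, k, algorithm, seed)


def clustering_accuracy(clusters: ClusteringResult | np.ndarray, labels) -> float:
    """Modal-label clustering accuracy as a percentage.

    Each cluster predicts the most frequent true label among its members
    (lexicographically smallest on ties); accuracy is the fraction of entities
    whose prediction equals their true label, times 100.
    """
    assign = clusters.assignment if isinstance(clusters, ClusteringResult) else np.asarray(clusters)
    labels = np.asarray(labels)
    if assign.shape != labels.shape:
        raise ValueError(f"cluster/label length mismatch: {assign.shape} vs {labels.shape}")
    correct = 0
    for c in np.unique(assign):
        members = labels[assign == c]
        types, counts = np.unique(members, return_counts=True)  # sorted -> lexicographic ties
        correct += int(counts.max())
    return 100.0 * correct / labels.size


def adjusted_rand_index(clusters: ClusteringResult | np.ndarray, labels) -> float:
    """Permutation-model adjusted Rand index between clustering and labels."""
    assign = clusters.assignment if isinstance(clusters, ClusteringResult) else np.asarray(clusters)
    labels = np.asarray(labels)
    if assign.shape != labels.shape:
        raise ValueError(f"cluster/label length mismatch: {assign.shape} vs {labels.shape}")
    return float(adjusted_rand_score(labels, assign))


def evaluate_embedding(embedding: np.ndarray, labels, k: int | None = None,
                       algorithm: str = "gmm", seed: int = 0) -> MetricReport:
    """Cluster an embedding (k defaults to the number of label classes) and
    report ACC and ARI against the given labels."""
    labels = np.asarray(labels)
    if k is None:
        k = int(np.unique(labels).size)
    res = cluster_embedding(embedding, k, algorithm=algorithm, seed=seed)
    return MetricReport(clustering_accuracy(res, labels),
                        adjusted_rand_index(res, labels), k, algorithm, seed)
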