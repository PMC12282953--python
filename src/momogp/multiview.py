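"""Manifold relevance determination: shared/private cell-latent dimensions.

In the multi-view model every view applies its own ARD weight vector w_v to
the *shared* cell embedding.  After training, the magnitude of w_v^r says
whether dimension r carries signal for view v; thresholding at a small delta
segments the latent space into dimensions shared by several views, private to
one view, or absent from all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MomoGPModel

__all__ = ["DimensionPartition", "partition_dimensions", "default_delta",
           "effective_ard_weights", "export_ard_report"]

#: default relative threshold: delta = DELTA_FRACTION * max learned weight
DELTA_FRACTION = 0.05


@dataclass
class DimensionPartition:
    """delta-rule segmentation of the cell-latent dimensions (0-based)."""

    shared: list[int]
    private_per_view: dict[int, list[int]]
    absent: list[int]
    delta: float

    def label(self, r: int) -> str:
        if r in self.shared:
            return "shared"
        for v, dims in self.private_per_view.items():
            if r in dims:
                return f"private_view{v}"
        return "absent"

    def to_dict(self) -> dict:
        return {
            "shared": self.shared,
            "private_per_view": {str(v): d for v, d in self.private_per_view.items()},
            "absent": self.absent,
            "delta": self.delta,
        }


def default_delta(w_per_view) -> float:
    """delta = 5% of the largest learned ARD weight over all views and dims.

    A relative default: ARD weights are unnormalized, so any absolute "close
    to zero" cutoff would be scale-fragile.
    """
    return DELTA_FRACTION * float(np.max(np.asarray(w_per_view)))


def effective_ard_weights(model: MomoGPModel) -> np.ndarray:
    """Scale-adjusted ARD weights: w_v^r times the variance of latent dim r.

    The learned latent dimensions carry arbitrary scales (the kernel only sees
    w^r (a^r - a'^r)^2, so a dimension can stretch while its raw weight
    shrinks).  Multiplying by the empirical variance of the cell embedding
    along each dimension gives the dimension's actual contribution to kernel
    distances, which is the quantity comparable across dimensions -- the same
    normalization as whitening the latent space to unit variance per
    dimension.  Shape (V, r1).
    """
    scale = model.params["A"].var(axis=0)
    return model.ard_weights() * scale[None, :]


def partition_dimensions(w_per_view, delta: float) -> DimensionPartition:
    """Classify each dimension by which views weight it above ``delta``.

    A dimension is shared when at least two views exceed delta (for two views
    this is exactly "both"), private to view v when only v exceeds it, and
    absent when no view does.
    """
    lens = {np.atleast_1d(np.asarray(w, dtype=float)).shape[0] for w in w_per_view}
    if len(lens) != 1:
        raise ValueError(f"ARD weight vectors have mismatched lengths: {sorted(lens)}")
    W = np.atleast_2d(np.asarray([np.asarray(w, dtype=float) for w in w_per_view]))
    if delta <= 0:
        raise ValueError("delta must be positive")
    V, r1 = W.shape
    above = W > delta
    shared, absent = [], []
    private: dict[int, list[int]] = {v: [] for v in range(V)}
    for r in range(r1):
        on = np.flatnonzero(above[:, r])
        if on.size >= 2:
            shared.append(r)
        elif on.size == 1:
            private[int(on[0])].append(r)
        else:
            absent.append(r)
    return DimensionPartition(shared, private, absent, float(delta))


def export_ard_report(model: MomoGPModel, path: str | None = None,
                      delta: float | None = None) -> pd.DataFrame:
    """Per-dimension ARD weights of every view plus the delta-rule label.

    Returns a DataFrame (one row per cell-latent dimension, one column per
    view, plus the partition label); writes it as TSV when ``path`` is given.
    """
    W = model.ard_weights()
    if delta is None:
        delta = default_delta(W)
    part = partition_dimensions(W, delta)
    cols = {f"w_{spec.name}": W[v] for v, spec in enumerate(model.view_specs)}
    df = pd.DataFrame(cols, index=pd.RangeIndex(model.r1, name="dimension"))
    df["label"] = [part.label(r) for r in range(model.r1)]
    if path is not None:
        df.to_csv(path, sep="\t")
    return df


def write_partition(part: DimensionPartition, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(part.to_dict(), fh, indent=1)
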