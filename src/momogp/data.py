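"""Matrix ingestion, triple-store representation, and cell-type labels.

Inputs are cell x feature matrices of already log-normalized values (the model
assumes a Gaussian likelihood, so preprocessing to log scale is the caller's
responsibility).  Supported on-disk formats: a MatrixMarket directory in the
CellRanger dialect (matrix.mtx + features.tsv + barcodes.tsv, optionally
gzipped sidecars) and a dense CSV with cell rows, feature columns and headers.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an on-disk matrix or its sidecars are malformed."""


@dataclass
class ViewMatrix:
    """One modality's dense cells x features matrix with ids."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x features)")
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.feature_ids)} feature ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"view '{self.view_name}' contains NaN/Inf values")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class TripleStore:
    """Observed entries of one view as (cell index, feature index, value) records.

    This is the model's training representation: the cell x feature grid
    vectorized cell-major (t = i * J + j), so one view's observations form a
    single long vector indexed by (i, j) pairs.
    """

    i: np.ndarray
    j: np.ndarray
    y: np.ndarray
    n_cells: int
    n_features: int
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.i.shape == self.j.shape == self.y.shape):
            raise ValueError("i, j, y must have identical shapes")
        if self.i.size:
            if self.i.min() < 0 or self.i.max() >= self.n_cells:
                raise ValueError("cell index out of range")
            if self.j.min() < 0 or self.j.max() >= self.n_features:
                raise ValueError("feature index out of range")
        flat = self.i * self.n_features + self.j
        if np.unique(flat).size != flat.size:
            raise ValueError("at most one triple per (i, j) pair")

    def __len__(self) -> int:
        return self.y.size

    def to_dense(self, fill: float = 0.0) -> np.ndarray:
        out = np.full((self.n_cells, self.n_features), fill)
        out[self.i, self.j] = self.y
        return out


@dataclass
class CellLabels:
    """cell_id -> cell-type label."""

    mapping: dict[str, str]

    @property
    def vocabulary(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def for_cells(self, cell_ids: list[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.mapping]
        if missing:
            raise KeyError(f"cells without labels: {missing[:5]}" +
                           (" ..." if len(missing) > 5 else ""))
        return np.array([self.mapping[c] for c in cell_ids])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_sidecar(directory: str, stem: str) -> list[str]:
    for name in (f"{stem}.tsv", f"{stem}.tsv.gz"):
        path = os.path.join(directory, name)
        if os.path.exists(path):
            opener = gzip.open if name.endswith(".gz") else open
            with opener(path, "rt") as fh:
                lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
            # CellRanger features.tsv carries extra columns (gene id, name, type)
            return [ln.split("\t")[0] for ln in lines]
    raise FormatError(f"missing sidecar {stem}.tsv(.gz) in {directory}")


def read_view(path: str, format: str | None = None, view_name: str | None = None) -> ViewMatrix:
    """Read one modality from disk.

    ``format`` is ``"mtx_dir"`` (directory with matrix.mtx + features/barcodes
    sidecars) or ``"csv"`` (dense, cell rows, header row of feature names,
    first column of cell ids); inferred from the path when omitted.  MTX
    matrices stored genes x cells (the CellRanger convention) are transposed
    automatically by matching sidecar lengths against the matrix dimensions.
    """
    if format is None:
        format = "mtx_dir" if os.path.isdir(path) else "csv"
    if view_name is None:
        view_name = os.path.basename(os.path.normpath(path)) or "view"

    if format == "mtx_dir":
        mtx_path = None
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            cand = os.path.join(path, name)
            if os.path.exists(cand):
                mtx_path = cand
                break
        if mtx_path is None:
            raise FormatError(f"missing matrix.mtx(.gz) in {path}")
        try:
            mat = scipy.io.mmread(mtx_path)
        except Exception as exc:  # pragma: no cover - scipy error text varies
            raise FormatError(f"could not parse {mtx_path}: {exc}") from exc
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        features = _read_sidecar(path, "features")
        barcodes = _read_sidecar(path, "barcodes")
        nr, nc = dense.shape
        if (nr, nc) == (len(barcodes), len(features)):
            pass  # already cells x features
        elif (nr, nc) == (len(features), len(barcodes)):
            dense = dense.T
        else:
            raise FormatError(
                f"{mtx_path}: matrix is {nr}x{nc} but sidecars give "
                f"{len(features)} features / {len(barcodes)} barcodes"
            )
        return ViewMatrix(dense, barcodes, features, view_name)

    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise FormatError(f"could not parse {path}: {exc}") from exc
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise FormatError(f"{path}: non-numeric entries in columns {list(bad)}")
        return ViewMatrix(values.astype(float), [str(c) for c in df.index],
                          [str(c) for c in df.columns], view_name)

    raise ValueError(f"unknown format {format!r}")


def write_view(view: ViewMatrix, path: str, format: str = "csv") -> None:
    """Write a view back to disk (round-trip counterpart of :func:`read_view`)."""
    if format == "csv":
        pd.DataFrame(view.values, index=view.cell_ids, columns=view.feature_ids).to_csv(path)
    elif format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"),
                         scipy.sparse.coo_matrix(view.values.T))  # features x cells on disk
        with open(os.path.join(path, "features.tsv"), "w") as fh:
            fh.write("\n".join(view.feature_ids) + "\n")
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(view.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str) -> CellLabels:
    """Read a TSV with columns (cell_id, cell_type); a header row is accepted."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cell_id", "cell_type"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cell_type"], dtype=str)
    return CellLabels(dict(zip(df["cell_id"], df["cell_type"])))


def write_labels(labels: CellLabels, path: str) -> None:
    pd.DataFrame(
        {"cell_id": list(labels.mapping), "cell_type": list(labels.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# triple store / cell intersection
# ---------------------------------------------------------------------------

def build_triple_store(view: ViewMatrix, keep_zeros: bool = True) -> TripleStore:
    """Vectorize a view into (i, j, y) triples, cell-major order.

    With ``keep_zeros=True`` (default) every grid entry becomes a triple, so
    the store is a lossless dense vectorization; with False, zero entries are
    dropped (the model then simply never sees them).
    """
    I, J = view.values.shape
    if keep_zeros:
        i, j = np.divmod(np.arange(I * J, dtype=np.int64), J)
        y = view.values.ravel()
    else:
        i, j = np.nonzero(view.values)
        order = np.argsort(i * J + j, kind="stable")
        i, j = i[order], j[order]
        y = view.values[i, j]
    return TripleStore(i, j, y, I, J, view.view_name)


def intersect_cells(views: list[ViewMatrix]) -> list[ViewMatrix]:
    """Restrict all views to their common cells, in the first view's order."""
    if len(views) < 2:
        raise ValueError("need at least two views to intersect")
    common = set(views[0].cell_ids)
    for v in views[1:]:
        common &= set(v.cell_ids)
    if not common:
        raise ValueError("views share no cells")
    order = [c for c in views[0].cell_ids if c in common]
    out = []
    for v in views:
        pos = {c: k for k, c in enumerate(v.cell_ids)}
        idx = np.array([pos[c] for c in order])
        out.append(ViewMatrix(v.values[idx], order, list(v.feature_ids), v.view_name))
    return out
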