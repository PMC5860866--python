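"""Representational dissimilarity matrices (RDMs) and their algebra.

An RDM is a square, symmetric, zero-diagonal matrix of pairwise
dissimilarities between labelled conditions (here, scene categories).
It is the common currency of every stage of the pipeline: model RDMs
are built from feature matrices, behavioral RDMs from arrangement
coordinates, and fMRI RDMs from cross-validated Mahalanobis distances.

The package-wide vectorization canon is the *lower triangle in row-major
order*: pairs (1,0), (2,0), (2,1), (3,0), ... Every module that consumes
RDM vectors assumes this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RDM",
    "SYMMETRY_TOL",
    "rdm_from_features",
    "rdm_subset",
    "vectorize_rdm",
    "unvectorize_rdm",
    "pair_labels",
    "correlate_rdms",
    "rank_transform",
    "read_rdm",
    "write_rdm",
    "read_feature_matrix",
]

#: Absolute tolerance for symmetry / zero-diagonal validation.
SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class RDM:
    """A labelled representational dissimilarity matrix.

    Parameters
    ----------
    labels : sequence of str
        Ordered condition identifiers, one per row/column.
    values : ndarray, shape (n, n)
        Dissimilarities. Must be symmetric within ``SYMMETRY_TOL`` with a
        zero diagonal. Entries may be negative (cross-validated distances
        are unbiased and can dip below zero).
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = tuple(str(l) for l in labels)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {values.shape[0]}x{values.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("RDM labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("RDM contains non-finite values")
        asym = np.max(np.abs(values - values.T)) if values.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"RDM asymmetric beyond tolerance: max |A - A.T| = {asym:g}")
        if values.size and np.max(np.abs(np.diag(values))) > SYMMETRY_TOL:
            raise ValueError("RDM diagonal must be zero")
        # symmetrize residual float noise and pin the diagonal
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def subset(self, keep: Sequence[str]) -> "RDM":
        return rdm_subset(self, keep)

    def vector(self) -> np.ndarray:
        return vectorize_rdm(self)

    def __eq__(self, other: object) -> bool:  # labels and values
        if not isinstance(other, RDM):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)


def rdm_from_features(features: pd.DataFrame, metric: str = "one_minus_pearson") -> RDM:
    """Build an RDM from an items x features matrix.

    Entry (i, j) is ``1 - Pearson's r`` between item i's and item j's
    feature vectors; the diagonal is exactly 0. This is the dissimilarity
    used for network-activation feature models.

    Parameters
    ----------
    features : DataFrame, shape (n_items, n_features)
        Index holds the item labels. No missing values allowed.
    metric : {"one_minus_pearson"}
    """
    if metric != "one_minus_pearson":
        raise ValueError(f"unsupported metric: {metric!r}")
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("feature matrix must be 2-D with >=2 items and >=1 feature")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    labels = [str(l) for l in features.index]
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance feature vector for item(s): {[labels[i] for i in dead]}"
        )
    r = np.corrcoef(X)
    values = 1.0 - r
    np.fill_diagonal(values, 0.0)
    return RDM(labels, values)


def rdm_subset(rdm: RDM, keep: Sequence[str]) -> RDM:
    """Principal submatrix of ``rdm`` restricted to ``keep``, in ``keep`` order."""
    keep = [str(k) for k in keep]
    if len(set(keep)) != len(keep):
        dupes = sorted({k for k in keep if keep.count(k) > 1})
        raise ValueError(f"duplicate labels in subset: {dupes}")
    index = {l: i for i, l in enumerate(rdm.labels)}
    missing = [k for k in keep if k not in index]
    if missing:
        raise KeyError(f"labels not in RDM: {missing}")
    idx = np.array([index[k] for k in keep], dtype=int)
    return RDM(keep, rdm.values[np.ix_(idx, idx)])


def pair_labels(labels: Sequence[str]) -> list[tuple[str, str]]:
    """Item-pair identifiers in the canonical lower-triangle row-major order."""
    return [(labels[i], labels[j]) for i in range(1, len(labels)) for j in range(i)]


def vectorize_rdm(rdm: RDM) -> np.ndarray:
    """Lower-triangle off-diagonal entries, row-major; length n(n-1)/2."""
    n = rdm.n_items
    return rdm.values[np.tril_indices(n, k=-1)].copy()


def unvectorize_rdm(vector: np.ndarray, labels: Sequence[str]) -> RDM:
    """Inverse of :func:`vectorize_rdm` for the given label order."""
    vector = np.asarray(vector, dtype=float)
    n = len(labels)
    if vector.shape != (n * (n - 1) // 2,):
        raise ValueError(
            f"vector length {vector.size} does not match {n} labels "
            f"(expected {n * (n - 1) // 2})"
        )
    values = np.zeros((n, n))
    idx = np.tril_indices(n, k=-1)
    values[idx] = vector
    values = values + values.T
    return RDM(labels, values)


def correlate_rdms(a: np.ndarray, b: np.ndarray, method: str = "pearson") -> float:
    """Correlation between two RDM vectors sharing the same pair ordering.

    ``spearman`` is Pearson on tie-averaged ranks. Raises on zero-variance
    input, since a correlation is then undefined.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs to correlate RDM vectors")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance RDM vector; correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method: {method!r}")


def rank_transform(rdm: RDM) -> RDM:
    """Rank-transformed copy (ties averaged), for display only.

    Rank-ordering compresses the dissimilarity scale and is never used in
    any statistic in this package; it exists because group-average RDMs
    are conventionally shown rank-scaled.
    """
    v = vectorize_rdm(rdm)
    ranks = stats.rankdata(v)
    return unvectorize_rdm(ranks, rdm.labels)


# ---------------------------------------------------------------------------
# I/O


def read_rdm(path: str) -> RDM:
    """Read an RDM from square CSV/TSV (labelled header row+column) or HDF5.

    HDF5 files must contain datasets ``labels`` and ``values``.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            labels = [
                l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]
            ]
            values = f["values"][()]
        return RDM(labels, values)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels disagree")
    return RDM(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_rdm(rdm: RDM, path: str) -> None:
    """Write an RDM as square CSV/TSV or HDF5 (datasets ``labels``, ``values``)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=np.array(rdm.labels, dtype="S"))
            f.create_dataset("values", data=rdm.values)
        return
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels).to_csv(path, sep=sep)


def read_feature_matrix(path: str) -> pd.DataFrame:
    """Read an items x features matrix (CSV/TSV, item labels in column 1, or HDF5)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            labels = [
                l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]
            ]
            values = f["values"][()]
        return pd.DataFrame(values, index=labels)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)
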