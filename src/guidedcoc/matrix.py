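"""Core containers: named cell-by-feature matrices and cluster assignments.

A :class:`CellFeatureMatrix` holds a non-negative ``n_cells x n_features``
matrix (UMI counts, TPM, or gene-activity scores) together with ordered,
unique row and column identifiers. Values may be a dense ``numpy`` array or
any ``scipy.sparse`` matrix; downstream code treats both uniformly.

A :class:`ClusterAssignment` is a total, hard labeling of ``m`` items into
``c`` clusters. :class:`CoClusterState` bundles the three assignments the
co-clustering optimizer manipulates: target cell clusters ``cy``, shared
feature clusters ``cz``, and the fixed source cell clusters ``cx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["CellFeatureMatrix", "ClusterAssignment", "CoClusterState"]


def _as_id_array(ids: Sequence[str], n: int, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or len(arr) != n:
        raise ValueError(f"{what}: expected {n} ids, got {len(arr)}")
    if len(set(arr)) != len(arr):
        raise ValueError(f"{what}: duplicate ids")
    return arr


@dataclass
class CellFeatureMatrix:
    """Named non-negative cells x features matrix.

    Parameters
    ----------
    values
        ``(n_cells, n_features)`` non-negative matrix, dense or sparse.
    cell_ids, feature_ids
        Ordered unique identifiers for rows and columns.
    transform
        Name of an already-applied value transform (e.g. ``"log2p1"``).
        Guards against accidental double application of the log transform.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    transform: Optional[str] = None

    def __post_init__(self) -> None:
        v = self.values
        if not sp.issparse(v):
            v = np.asarray(v, dtype=float)
            self.values = v
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, q = v.shape
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i}" for i in range(n)], dtype=object)
        if self.feature_ids is None:
            self.feature_ids = np.array([f"feat{j}" for j in range(q)], dtype=object)
        self.cell_ids = _as_id_array(self.cell_ids, n, "cell_ids")
        self.feature_ids = _as_id_array(self.feature_ids, q, "feature_ids")
        mn = v.min() if not sp.issparse(v) else (v.data.min() if v.nnz else 0.0)
        if mn < 0:
            raise ValueError("matrix entries must be non-negative")
        if self.total() <= 0:
            raise ValueError("matrix must contain at least one positive entry")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def total(self) -> float:
        return float(self.values.sum())

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def subset_features(self, index: np.ndarray, new_ids: Optional[Sequence[str]] = None) -> "CellFeatureMatrix":
        """Column subset/reorder by integer index, optionally renaming ids."""
        vals = self.values[:, index] if not sp.issparse(self.values) else self.values.tocsc()[:, index].tocsr()
        ids = np.asarray(new_ids, dtype=object) if new_ids is not None else self.feature_ids[index]
        return CellFeatureMatrix(vals, self.cell_ids.copy(), ids, transform=self.transform)


@dataclass
class ClusterAssignment:
    """Hard assignment of ``m`` items into clusters ``0..n_clusters-1``."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.n_clusters):
            raise ValueError("labels out of range")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def empty_clusters(self) -> np.ndarray:
        return np.flatnonzero(self.counts() == 0)

    def indicator(self) -> sp.csr_matrix:
        """Sparse one-hot ``(m, n_clusters)`` membership matrix."""
        m = len(self.labels)
        return sp.csr_matrix(
            (np.ones(m), (np.arange(m), self.labels)), shape=(m, self.n_clusters)
        )

    def with_labels(self, labels: np.ndarray) -> "ClusterAssignment":
        return ClusterAssignment(labels, self.n_clusters)


@dataclass
class CoClusterState:
    """Assignments manipulated by Stage 1: (cy, cz) free, cx fixed."""

    cy: ClusterAssignment
    cz: ClusterAssignment
    cx: ClusterAssignment

    def replace(self, **kw) -> "CoClusterState":
        return replace(self, **kw)
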