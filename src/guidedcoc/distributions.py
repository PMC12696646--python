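"""Probability-space primitives for information-theoretic co-clustering.

The empirical joint distribution of a count matrix is obtained by dividing
by its grand total, so ``P(Y=y, Z=z)`` is the fraction of total signal that
cell ``y`` carries on feature ``z``. Co-clustering compresses this joint
through a pair of hard clusterings ``(CY, CZ)``; the quality of the
compression is the KL divergence between ``P`` and a reference ``P*`` that
re-expands the cluster-level joint assuming within-cluster independence:

    P*(y, z) = Pt(yt, zt) * [P(y)/Pt(yt)] * [P(z)/Pt(zt)],

with ``yt = CY(y)``, ``zt = CZ(z)`` and ``Pt`` the cluster-level
(coarse-grained) joint. The loss ``D_KL(P || P*)`` equals the mutual
information lost by coarse-graining, ``I(Y;Z) - I(Yt;Zt)``, and decomposes
into weighted per-row (or per-column) conditional KL terms — the quantities
the block-coordinate optimizer minimizes per cell and per feature.

All KL quantities use natural logarithms and the convention
``0 * log(0/x) = 0``; zero entries of ``P`` never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import xlogy

from .matrix import CellFeatureMatrix, ClusterAssignment

__all__ = [
    "JointDistribution",
    "normalize_joint",
    "coarse_joint",
    "reference_joint",
    "kl_cocluster_loss",
    "conditional_kl_row",
    "conditional_kl_col",
]


@dataclass
class JointDistribution:
    """Normalized joint ``P(Y, Z)`` with cached marginals."""

    P: np.ndarray | sp.spmatrix
    row_marginal: np.ndarray
    col_marginal: np.ndarray

    @property
    def shape(self):
        return self.P.shape

    def nonzeros(self):
        """COO triplets (rows, cols, values) of the nonzero entries."""
        if sp.issparse(self.P):
            coo = self.P.tocoo()
            return coo.row, coo.col, coo.data
        r, c = np.nonzero(self.P)
        return r, c, np.asarray(self.P)[r, c]

    def dense(self) -> np.ndarray:
        return np.asarray(self.P.todense()) if sp.issparse(self.P) else self.P


def normalize_joint(m: CellFeatureMatrix | np.ndarray | sp.spmatrix) -> JointDistribution:
    """Empirical joint distribution: the matrix divided by its grand total."""
    values = m.values if isinstance(m, CellFeatureMatrix) else m
    total = float(values.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero matrix into a distribution")
    P = values / total
    if sp.issparse(P):
        P = P.tocsr()
        row_m = np.asarray(P.sum(axis=1)).ravel()
        col_m = np.asarray(P.sum(axis=0)).ravel()
    else:
        P = np.asarray(P, dtype=float)
        row_m = P.sum(axis=1)
        col_m = P.sum(axis=0)
    return JointDistribution(P, row_m, col_m)


def _check_shapes(P: JointDistribution, rows: ClusterAssignment, cols: ClusterAssignment) -> None:
    n, q = P.shape
    if len(rows) != n:
        raise ValueError(f"row clustering covers {len(rows)} items, matrix has {n} rows")
    if len(cols) != q:
        raise ValueError(f"column clustering covers {len(cols)} items, matrix has {q} columns")


def coarse_joint(
    P: JointDistribution, row_clusters: ClusterAssignment, col_clusters: ClusterAssignment
) -> np.ndarray:
    """Cluster-level joint ``Pt(Yt, Zt)``: block sums of ``P``. Dense (c_r, c_c)."""
    _check_shapes(P, row_clusters, col_clusters)
    R = row_clusters.indicator()
    C = col_clusters.indicator()
    out = R.T @ P.P @ C
    return np.asarray(out.todense()) if sp.issparse(out) else np.asarray(out)


def reference_joint(
    P: JointDistribution, row_clusters: ClusterAssignment, col_clusters: ClusterAssignment
) -> JointDistribution:
    """Independence-adjusted reference ``P*`` of the co-clustering.

    Preserves the row and column marginals of ``P`` exactly while carrying
    only the cluster-level dependence structure. Materialized dense.
    """
    Pt = coarse_joint(P, row_clusters, col_clusters)
    pt_row = Pt.sum(axis=1)
    pt_col = Pt.sum(axis=0)
    row_mass = np.bincount(row_clusters.labels, weights=P.row_marginal, minlength=row_clusters.n_clusters)
    col_mass = np.bincount(col_clusters.labels, weights=P.col_marginal, minlength=col_clusters.n_clusters)
    for name, mass, count in (
        ("row", row_mass, row_clusters.counts()),
        ("column", col_mass, col_clusters.counts()),
    ):
        bad = np.flatnonzero((count > 0) & (mass <= 0))
        if bad.size:
            raise ValueError(f"{name} cluster {int(bad[0])} has zero total probability mass")
    pr = pt_row[row_clusters.labels]
    pc = pt_col[col_clusters.labels]
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(pr > 0, P.row_marginal / np.where(pr > 0, pr, 1.0), 0.0)
        cf = np.where(pc > 0, P.col_marginal / np.where(pc > 0, pc, 1.0), 0.0)
    block = Pt[np.ix_(row_clusters.labels, col_clusters.labels)]
    Pstar = block * np.outer(rf, cf)
    return JointDistribution(Pstar, Pstar.sum(axis=1), Pstar.sum(axis=0))


def _cluster_stats(P: JointDistribution, rows: ClusterAssignment, cols: ClusterAssignment):
    """Coarse joint plus its marginals, shared by the KL routines."""
    Pt = coarse_joint(P, rows, cols)
    return Pt, Pt.sum(axis=1), Pt.sum(axis=0)


def kl_cocluster_loss(
    P: JointDistribution, row_clusters: ClusterAssignment, col_clusters: ClusterAssignment
) -> float:
    """``D_KL(P || P*)`` without materializing ``P*``.

    For every nonzero entry ``p = P(y, z)`` the reference factorizes, so

        p * log(p / P*(y,z)) = p * [log p - log Pt(yt,zt)
                                     - log(P(y)/Pt(yt)) - log(P(z)/Pt(zt))].

    Nonzero ``p`` inside a block forces the block mass and all marginals
    involved to be positive, so every log is finite.
    """
    Pt, pt_row, pt_col = _cluster_stats(P, row_clusters, col_clusters)
    r, c, p = P.nonzeros()
    if len(p) == 0:
        return 0.0
    yt = row_clusters.labels[r]
    zt = col_clusters.labels[c]
    val = p * (
        np.log(p)
        - np.log(Pt[yt, zt])
        - np.log(P.row_marginal[r] / pt_row[yt])
        - np.log(P.col_marginal[c] / pt_col[zt])
    )
    return float(max(val.sum(), 0.0))


def conditional_kl_row(
    P: JointDistribution,
    y: int,
    candidate_cluster: int,
    row_clusters: ClusterAssignment,
    col_clusters: ClusterAssignment,
) -> float:
    """``D_KL(P(Z|Y=y) || P*(Z | Yt=i))`` for a candidate row cluster ``i``.

    The candidate-conditional reference is
    ``P*(z | Yt=i) = [P(z)/Pt(Zt=CZ(z))] * Pt(Zt=CZ(z) | Yt=i)``.
    Weighted by ``P(Y=y)`` and summed over rows (with ``i = CY(y)``), these
    terms reassemble the full co-clustering loss.
    """
    py = P.row_marginal[y]
    if py <= 0:
        raise ValueError(f"row {y} has zero probability mass")
    Pt, pt_row, pt_col = _cluster_stats(P, row_clusters, col_clusters)
    if pt_row[candidate_cluster] <= 0:
        raise ValueError(f"candidate row cluster {candidate_cluster} is empty (zero mass)")
    row = np.asarray(P.P[[y]].todense()).ravel() if sp.issparse(P.P) else np.asarray(P.P)[y]
    nz = np.flatnonzero(row)
    cond = row[nz] / py
    zt = col_clusters.labels[nz]
    ref = (P.col_marginal[nz] / pt_col[zt]) * (Pt[candidate_cluster, zt] / pt_row[candidate_cluster])
    if np.any(ref <= 0):
        raise ValueError(
            f"reference conditional is zero where the row has mass "
            f"(row {y}, candidate cluster {candidate_cluster})"
        )
    return float(np.sum(cond * np.log(cond / ref)))


def conditional_kl_col(
    P: JointDistribution,
    z: int,
    candidate_cluster: int,
    row_clusters: ClusterAssignment,
    col_clusters: ClusterAssignment,
) -> float:
    """``D_KL(P(Y|Z=z) || P*(Y | Zt=j))`` — mirror of the row conditional."""
    Pt_mat = P.P.T.tocsr() if sp.issparse(P.P) else np.ascontiguousarray(P.P.T)
    PT = JointDistribution(Pt_mat, P.col_marginal, P.row_marginal)
    return conditional_kl_row(PT, z, candidate_cluster, col_clusters, row_clusters)


def mutual_information(P: np.ndarray) -> float:
    """``I(Y;Z)`` of a (dense) joint probability matrix, natural log.

    Brute-force reference used by tests; also the basis of the identity
    ``kl_cocluster_loss == I(Y;Z) - I(Yt;Zt)``.
    """
    P = np.asarray(P, dtype=float)
    pr = P.sum(axis=1, keepdims=True)
    pc = P.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(P > 0, P / (pr @ pc), 1.0)
    return float(xlogy(P, ratio).sum())
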