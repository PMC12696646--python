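"""Stage 1: integrative co-clustering by block-coordinate descent.

Minimizes the weighted objective

    L(CY, CZ) = L_Rt(CY, CZ) + alpha * L_At(CY, CZ) + beta * L_Rs(CZ | CX)

where each term is the KL co-clustering loss of one matrix: the target
scRNA-seq matrix ``R_t``, the row-paired gene-activity matrix ``A_t``
(sharing both cell clusters ``CY`` and feature clusters ``CZ`` with
``R_t``), and the source scRNA-seq matrix ``R_s``, whose cell clustering
``CX`` is known and fixed. The shared feature clustering ``CZ`` is the
conduit through which the source's structure informs the target.

Each iteration is one synchronous sweep over cells (update ``CY`` against
the cluster statistics of the previous state) followed by a refresh, then
one synchronous sweep over features (update ``CZ``), then a refresh. Both
sweeps are exact per-item minimizations of the objective's conditional-KL
decomposition, so the recorded objective never increases. Emptied clusters
are repaired by donating the item with the largest current conditional-KL
contribution; since moving an item into an empty cluster refines the
partition, the repair also never increases the objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .distributions import JointDistribution, kl_cocluster_loss, normalize_joint
from .matrix import CellFeatureMatrix, ClusterAssignment, CoClusterState

__all__ = ["Stage1Config", "Stage1Result", "objective", "update_cy", "update_cz", "initialize", "fit"]

logger = logging.getLogger(__name__)

# Surrogate for log(0) in cost matrices: large enough that a cluster with no
# mass on a needed feature block is never chosen over a finite-cost cluster,
# small enough that products with probabilities stay finite.
_LOG_ZERO = -1e30


@dataclass
class Stage1Config:
    """Hyperparameters of the Stage-1 objective and optimizer.

    ``alpha`` weights the gene-activity modality, ``beta`` the source
    domain; ``k_features`` is the number of shared feature clusters K and
    ``n_target_clusters`` the number of target cell clusters. Defaults
    follow the method's empirical setting (K=12, alpha=0.8, beta=1).
    """

    n_target_clusters: int = 8
    k_features: int = 12
    alpha: float = 0.8
    beta: float = 1.0
    max_iter: int = 30
    tol: float = 1e-6
    seed: int = 0
    init_method: str = "kmeans"  # kmeans | random | provided
    polish: bool = True  # single-move descent to a true local minimum

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_target_clusters < 1 or self.k_features < 1:
            raise ValueError("cluster counts must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init_method not in ("kmeans", "random", "provided"):
            raise ValueError(f"unknown init_method {self.init_method!r}")


@dataclass
class Stage1Result:
    state: CoClusterState
    objective_trace: List[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def objective(
    PR_t: JointDistribution,
    PA_t: JointDistribution,
    PR_s: JointDistribution,
    state: CoClusterState,
    cfg: Stage1Config,
) -> float:
    """Weighted sum of the three KL co-clustering losses."""
    if PR_t.shape != PA_t.shape:
        raise ValueError("R_t and A_t joints must have identical shape")
    if PR_s.shape[1] != PR_t.shape[1]:
        raise ValueError("R_s must share the feature axis with R_t")
    val = kl_cocluster_loss(PR_t, state.cy, state.cz)
    if cfg.alpha > 0:
        val += cfg.alpha * kl_cocluster_loss(PA_t, state.cy, state.cz)
    if cfg.beta > 0:
        val += cfg.beta * kl_cocluster_loss(PR_s, state.cx, state.cz)
    return val


# ---------------------------------------------------------------------------
# sweep machinery

def _agg_cols(P: JointDistribution, cz: ClusterAssignment) -> np.ndarray:
    """(n, K) matrix T with T[y,k] = sum_{z in feature cluster k} P(y,z)."""
    T = P.P @ cz.indicator()
    return np.asarray(T.todense()) if sp.issparse(T) else np.asarray(T)

def _agg_rows(P: JointDistribution, cy: ClusterAssignment) -> np.ndarray:
    """(N, q) matrix S with S[i,z] = sum_{y in cell cluster i} P(y,z)."""
    S = cy.indicator().T @ P.P
    return np.asarray(S.todense()) if sp.issparse(S) else np.asarray(S)


def _log_cond(Pt: np.ndarray, axis: int) -> np.ndarray:
    """log of Pt normalized along ``axis``; zeros mapped to _LOG_ZERO."""
    denom = Pt.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(np.where(Pt > 0, Pt, 1.0) / np.where(denom > 0, denom, 1.0))
    out[Pt <= 0] = _LOG_ZERO
    return out


def _row_cost(P: JointDistribution, cy: ClusterAssignment, cz: ClusterAssignment) -> np.ndarray:
    """(n, N) cost matrix for reassigning each row, up to per-row constants.

    cost[y, i] = - sum_k T[y,k] * log Pt(Zt=k | Yt=i); the dropped constants
    do not depend on the candidate cluster i, so argmin is unaffected.
    """
    T = _agg_cols(P, cz)
    Pt = _agg_rows(JointDistribution(T, T.sum(axis=1), T.sum(axis=0)), cy)  # (N, K)
    return -(T @ _log_cond(Pt, axis=1).T)


def _col_cost(P: JointDistribution, row_clusters: ClusterAssignment, cz: ClusterAssignment) -> np.ndarray:
    """(q, K) cost matrix for reassigning each column, up to constants."""
    S = _agg_rows(P, row_clusters)  # (N, q)
    Pt = S @ cz.indicator()
    Pt = np.asarray(Pt.todense()) if sp.issparse(Pt) else np.asarray(Pt)  # (N, K)
    return -(S.T @ _log_cond(Pt, axis=0))


def _row_contrib(P: JointDistribution, cy: ClusterAssignment, cz: ClusterAssignment) -> np.ndarray:
    """Per-row weighted conditional KL: P(y) * D_KL(P(Z|y) || P*(Z|Yt)).

    Summing this vector gives the full co-clustering loss (row form of the
    conditional decomposition); used by the empty-cluster repair heuristic.
    """
    r, c, p = P.nonzeros()
    Pt = _agg_rows(JointDistribution(_agg_cols(P, cz), None, None), cy)  # type: ignore[arg-type]
    pt_row = Pt.sum(axis=1)
    pt_col = Pt.sum(axis=0)
    yt = cy.labels[r]
    zt = cz.labels[c]
    terms = p * (
        np.log(p)
        - np.log(Pt[yt, zt])
        - np.log(P.row_marginal[r] / pt_row[yt])
        - np.log(P.col_marginal[c] / pt_col[zt])
    )
    return np.bincount(r, weights=terms, minlength=P.shape[0])


def _col_contrib(P: JointDistribution, row_clusters: ClusterAssignment, cz: ClusterAssignment) -> np.ndarray:
    r, c, p = P.nonzeros()
    Pt = _agg_rows(JointDistribution(_agg_cols(P, cz), None, None), row_clusters)  # type: ignore[arg-type]
    pt_row = Pt.sum(axis=1)
    pt_col = Pt.sum(axis=0)
    yt = row_clusters.labels[r]
    zt = cz.labels[c]
    terms = p * (
        np.log(p)
        - np.log(Pt[yt, zt])
        - np.log(P.row_marginal[r] / pt_row[yt])
        - np.log(P.col_marginal[c] / pt_col[zt])
    )
    return np.bincount(c, weights=terms, minlength=P.shape[1])


def _repair_empty(labels: np.ndarray, n_clusters: int, contrib: np.ndarray) -> np.ndarray:
    """Keep every cluster non-empty by donating high-loss items.

    Each empty cluster receives the item with the largest current
    conditional-KL contribution among clusters that can spare one. Moving an
    item to an empty cluster splits its old cluster, a refinement, so the
    objective cannot increase.
    """
    labels = labels.copy()
    counts = np.bincount(labels, minlength=n_clusters)
    for c in np.flatnonzero(counts == 0):
        movable = counts[labels] > 1
        if not movable.any():
            logger.warning("cannot repair empty cluster %d: no donor available", c)
            continue
        cand = np.where(movable, contrib, -np.inf)
        donor = int(np.argmax(cand))
        counts[labels[donor]] -= 1
        labels[donor] = c
        counts[c] += 1
    return labels


def update_cy(
    PR_t: JointDistribution, PA_t: JointDistribution, state: CoClusterState, cfg: Stage1Config
) -> CoClusterState:
    """Synchronous re-assignment of every target cell to its argmin cluster.

    Cluster reference conditionals come from ``state`` (pre-sweep), so the
    sweep is a batch update; ties go to the lowest cluster index.
    """
    cost = _row_cost(PR_t, state.cy, state.cz)
    if cfg.alpha > 0:
        cost = cost + cfg.alpha * _row_cost(PA_t, state.cy, state.cz)
    labels = np.argmin(cost, axis=1)
    contrib = _row_contrib(PR_t, state.cy, state.cz)
    if cfg.alpha > 0:
        contrib = contrib + cfg.alpha * _row_contrib(PA_t, state.cy, state.cz)
    labels = _repair_empty(labels, state.cy.n_clusters, contrib)
    return state.replace(cy=state.cy.with_labels(labels))


def update_cz(
    PR_t: JointDistribution,
    PA_t: JointDistribution,
    PR_s: JointDistribution,
    state: CoClusterState,
    cfg: Stage1Config,
) -> CoClusterState:
    """Synchronous re-assignment of every shared feature to its argmin cluster.

    The per-feature cost sums conditional column KLs across all three
    matrices: target RNA (rows clustered by CY), gene activity (CY), and
    source RNA (rows clustered by the fixed CX).
    """
    cost = _col_cost(PR_t, state.cy, state.cz)
    if cfg.alpha > 0:
        cost = cost + cfg.alpha * _col_cost(PA_t, state.cy, state.cz)
    if cfg.beta > 0:
        cost = cost + cfg.beta * _col_cost(PR_s, state.cx, state.cz)
    labels = np.argmin(cost, axis=1)
    contrib = _col_contrib(PR_t, state.cy, state.cz)
    if cfg.alpha > 0:
        contrib = contrib + cfg.alpha * _col_contrib(PA_t, state.cy, state.cz)
    if cfg.beta > 0:
        contrib = contrib + cfg.beta * _col_contrib(PR_s, state.cx, state.cz)
    labels = _repair_empty(labels, state.cz.n_clusters, contrib)
    return state.replace(cz=state.cz.with_labels(labels))


# ---------------------------------------------------------------------------
# single-move polish
#
# The batch sweeps minimize per-item conditional KL against the *pre-sweep*
# cluster references, so their fixed point need not be a local minimum of
# the true objective under single reassignments. After the sweeps converge,
# a polish phase applies exact single-move descent: moving one item only
# changes the coarse joint Pt (and one pair of its cluster marginals), so
# the objective delta is computable in O(K) per candidate cluster.

from scipy.special import xlogy as _xlogy


def _coarse_terms(Pt_rows: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """I-contribution of coarse rows: sum_k Pt[k] * log(Pt[k]/(r*c[k]))."""
    Pt_rows = np.maximum(Pt_rows, 0.0)
    r = np.maximum(np.atleast_1d(r), 0.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Pt_rows > 0, Pt_rows / np.where(r * c > 0, r * c, 1.0), 1.0)
    return _xlogy(Pt_rows, ratio).sum(axis=1)


def _polish_pass_rows(Ts, weights, labels, counts):
    """One deterministic sweep of exact single-move descent over rows.

    ``Ts``: per-matrix (n, K) cluster-aggregated joints; moving row ``y``
    between row clusters shifts its T-row between rows of each coarse Pt.
    Returns (labels, n_moves, total_delta).
    """
    n = Ts[0].shape[0]
    N = counts.size
    Pts = []
    for T in Ts:
        ind = sp.csr_matrix((np.ones(n), (labels, np.arange(n))), shape=(N, n))
        Pts.append(np.asarray(ind @ T))
    rs = [Pt.sum(axis=1) for Pt in Pts]
    cs = [Pt.sum(axis=0) for Pt in Pts]
    F = [_coarse_terms(Pt, r, c) for Pt, r, c in zip(Pts, rs, cs)]
    moves = 0
    total_delta = 0.0
    for y in range(n):
        a = labels[y]
        if counts[a] <= 1:
            continue  # emptying a cluster merges partitions; never improves
        delta = np.zeros(N)
        for T, w, Pt, r, c, f in zip(Ts, weights, Pts, rs, cs, F):
            t = T[y]
            s = t.sum()
            f_a_new = _coarse_terms((Pt[a] - t)[None, :], r[a] - s, c)[0]
            f_b_new = _coarse_terms(Pt + t[None, :], r + s, c)
            # loss delta = -(delta I of the coarse joint), per matrix
            delta += -w * (f_a_new + f_b_new - f[a] - f)
        delta[a] = 0.0
        b = int(np.argmin(delta))
        if delta[b] < -1e-12:
            for T, Pt, r, c, f in zip(Ts, Pts, rs, cs, F):
                t = T[y]
                s = t.sum()
                Pt[a] -= t
                Pt[b] += t
                np.maximum(Pt[a], 0.0, out=Pt[a])
                r[a] -= s
                r[b] += s
                f[a] = _coarse_terms(Pt[[a]], r[a], c)[0]
                f[b] = _coarse_terms(Pt[[b]], r[b], c)[0]
            counts[a] -= 1
            counts[b] += 1
            labels[y] = b
            total_delta += delta[b]
            moves += 1
    return labels, moves, total_delta


def _polish(PR_t, PA_t, PR_s, state: CoClusterState, cfg: Stage1Config,
            max_passes: int = 100):
    """Alternate exact single-move descent over cells and features until no
    move improves the objective. Deterministic; objective non-increasing."""
    cy_lab = state.cy.labels.copy()
    cz_lab = state.cz.labels.copy()
    for _ in range(max_passes):
        cz = ClusterAssignment(cz_lab, state.cz.n_clusters)
        Ts = [_agg_cols(PR_t, cz)]
        weights = [1.0]
        if cfg.alpha > 0:
            Ts.append(_agg_cols(PA_t, cz))
            weights.append(cfg.alpha)
        cy_lab, mv_y, _ = _polish_pass_rows(
            Ts, weights, cy_lab, np.bincount(cy_lab, minlength=state.cy.n_clusters)
        )
        # feature moves: transpose roles — rows become features, aggregated
        # over the relevant row clustering of each matrix
        cy = ClusterAssignment(cy_lab, state.cy.n_clusters)
        Ss = [_agg_rows(PR_t, cy).T]
        weights = [1.0]
        if cfg.alpha > 0:
            Ss.append(_agg_rows(PA_t, cy).T)
            weights.append(cfg.alpha)
        if cfg.beta > 0:
            Ss.append(_agg_rows(PR_s, state.cx).T)
            weights.append(cfg.beta)
        cz_lab, mv_z, _ = _polish_pass_rows(
            Ss, weights, cz_lab, np.bincount(cz_lab, minlength=state.cz.n_clusters)
        )
        if mv_y == 0 and mv_z == 0:
            break
    return state.replace(
        cy=state.cy.with_labels(cy_lab), cz=state.cz.with_labels(cz_lab)
    )


# ---------------------------------------------------------------------------
# initialization

def _ensure_nonempty(labels: np.ndarray, k: int) -> np.ndarray:
    """Deterministically fill empty clusters from the largest clusters."""
    labels = labels.copy()
    counts = np.bincount(labels, minlength=k)
    for c in np.flatnonzero(counts == 0):
        donor_cluster = int(np.argmax(counts))
        donor = int(np.flatnonzero(labels == donor_cluster)[-1])
        counts[donor_cluster] -= 1
        labels[donor] = c
        counts[c] += 1
    return labels


def initialize(
    R_t: CellFeatureMatrix,
    R_s: CellFeatureMatrix,
    cx: ClusterAssignment,
    cfg: Stage1Config,
    cy_labels: Optional[np.ndarray] = None,
    cz_labels: Optional[np.ndarray] = None,
) -> CoClusterState:
    """Build the starting (CY, CZ) assignments.

    ``kmeans``: CY from k-means on log2(1+x) cell profiles of ``R_t`` (the
    matrix is used as-is when already log-transformed); CZ from k-means on
    each feature's source-cluster conditional profile ``P_Rs(Xt | z)``,
    which groups features by how their mass distributes across the known
    source populations. ``random``: seeded uniform labels with every
    cluster guaranteed non-empty. ``provided``: validated user labels.
    """
    n_t, K = cfg.n_target_clusters, cfg.k_features
    n, q = R_t.n_cells, R_t.n_features
    if not (1 <= K <= q):
        raise ValueError(f"k_features must be in [1, {q}]")
    if not (1 <= n_t <= n):
        raise ValueError(f"n_target_clusters must be in [1, {n}]")
    if cfg.init_method == "provided":
        if cy_labels is None or cz_labels is None:
            raise ValueError("init_method='provided' requires cy_labels and cz_labels")
        cy = ClusterAssignment(np.asarray(cy_labels), n_t)
        cz = ClusterAssignment(np.asarray(cz_labels), K)
        return CoClusterState(cy=cy, cz=cz, cx=cx)
    if cfg.init_method == "random":
        rng = np.random.default_rng(cfg.seed)
        cy_lab = rng.integers(0, n_t, size=n)
        cy_lab[rng.permutation(n)[:n_t]] = np.arange(n_t)
        cz_lab = rng.integers(0, K, size=q)
        cz_lab[rng.permutation(q)[:K]] = np.arange(K)
        return CoClusterState(
            cy=ClusterAssignment(cy_lab, n_t), cz=ClusterAssignment(cz_lab, K), cx=cx
        )
    # kmeans
    X = R_t.dense()
    if R_t.transform is None:
        X = np.log2(X + 1.0)
    km_y = KMeans(n_clusters=n_t, n_init=10, random_state=cfg.seed)
    cy_lab = _ensure_nonempty(km_y.fit_predict(X), n_t)
    Ps = normalize_joint(R_s)
    S = _agg_rows(Ps, cx)  # (N_s, q)
    colsum = S.sum(axis=0)
    prof = np.where(colsum > 0, S / np.where(colsum > 0, colsum, 1.0), 1.0 / S.shape[0]).T
    km_z = KMeans(n_clusters=K, n_init=10, random_state=cfg.seed + 1)
    cz_lab = _ensure_nonempty(km_z.fit_predict(prof), K)
    return CoClusterState(
        cy=ClusterAssignment(cy_lab, n_t), cz=ClusterAssignment(cz_lab, K), cx=cx
    )


def fit(
    R_t: CellFeatureMatrix,
    A_t: CellFeatureMatrix,
    R_s: CellFeatureMatrix,
    cx: ClusterAssignment,
    cfg: Stage1Config,
    cy_init: Optional[np.ndarray] = None,
    cz_init: Optional[np.ndarray] = None,
) -> Stage1Result:
    """Run Stage-1 block-coordinate descent to convergence.

    One iteration = CY sweep + refresh + CZ sweep + refresh; the objective
    is recorded after each full iteration and the loop stops when its
    relative change drops below ``cfg.tol`` or ``cfg.max_iter`` is reached.
    Fully deterministic given ``cfg.seed``.
    """
    if R_t.n_cells != A_t.n_cells or not np.array_equal(R_t.cell_ids, A_t.cell_ids):
        raise ValueError("R_t and A_t must be row-paired (same cells, same order)")
    for other, name in ((A_t, "A_t"), (R_s, "R_s")):
        if not np.array_equal(R_t.feature_ids, other.feature_ids):
            raise ValueError(f"{name} features are not aligned with R_t")
    if len(cx) != R_s.n_cells:
        raise ValueError("cx must label every source cell")
    PR_t = normalize_joint(R_t)
    PA_t = normalize_joint(A_t)
    PR_s = normalize_joint(R_s)
    state = initialize(R_t, R_s, cx, cfg, cy_labels=cy_init, cz_labels=cz_init)
    prev = objective(PR_t, PA_t, PR_s, state, cfg)
    logger.info("stage1 initial objective: %.6g", prev)
    trace: List[float] = []
    converged = False
    n_iter = 0
    for it in range(1, cfg.max_iter + 1):
        state = update_cy(PR_t, PA_t, state, cfg)
        state = update_cz(PR_t, PA_t, PR_s, state, cfg)
        obj = objective(PR_t, PA_t, PR_s, state, cfg)
        trace.append(obj)
        n_iter = it
        rel = abs(obj - prev) / max(prev, 1e-12)
        logger.info("stage1 iter %d: objective=%.6g rel_change=%.3g", it, obj, rel)
        prev = obj
        if rel < cfg.tol:
            converged = True
            break
    if cfg.polish:
        polished = _polish(PR_t, PA_t, PR_s, state, cfg)
        if not (
            np.array_equal(polished.cy.labels, state.cy.labels)
            and np.array_equal(polished.cz.labels, state.cz.labels)
        ):
            state = polished
            obj = objective(PR_t, PA_t, PR_s, state, cfg)
            logger.info("stage1 polish: objective=%.6g", obj)
            trace.append(obj)
    return Stage1Result(state=state, objective_trace=trace, converged=converged, n_iter=n_iter)
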