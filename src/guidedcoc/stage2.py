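"""Stage 2: cross-domain cluster matching by averaged Jensen-Shannon divergence.

After Stage 1, each source cluster (known labels ``CX``) and each learned
target cluster (``CY``) is summarized by its feature profile: the
normalized sum of its cells' rows over the shared genes. Pairs are scored
with the averaged Jensen-Shannon divergence (AJSD): the mean base-2 JSD
over ``n_trials`` recomputations from random subsamples of each cluster's
cells, which penalizes matches that are unstable under resampling. Only
pairs with AJSD below ``tau_jsd`` are eligible. Exclusive one-to-one
matches are found by a greedy pass repeated over ``n_shuffles`` random
permutations of the target-cluster order, keeping the configuration with
the smallest total AJSD; populations private to one domain simply remain
unmatched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import rel_entr

from .matrix import CellFeatureMatrix, ClusterAssignment

__all__ = [
    "MatchConfig",
    "ClusterProfile",
    "MatchResult",
    "cluster_profile",
    "jsd",
    "ajsd",
    "ajsd_matrix",
    "match",
]

logger = logging.getLogger(__name__)


@dataclass
class MatchConfig:
    """Matching hyperparameters; defaults follow the method's setting
    (25 trials, 25 shuffles, tau = 0.45 on the base-2 [0, 1] JSD scale)."""

    n_trials: int = 25
    n_shuffles: int = 25
    tau_jsd: float = 0.45
    subsample_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_shuffles < 1:
            raise ValueError("n_trials and n_shuffles must be positive")
        if not (0.0 <= self.tau_jsd <= 1.0):
            raise ValueError("tau_jsd must lie in [0, 1]")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass
class ClusterProfile:
    distribution: np.ndarray
    cluster_id: int
    domain: str  # "source" | "target"
    n_cells: int


@dataclass
class MatchResult:
    matches: List[Tuple[int, int, float]]
    unmatched_source: List[int]
    unmatched_target: List[int]
    total_ajsd: float
    ajsd: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def cluster_profile(
    m: CellFeatureMatrix,
    labels: ClusterAssignment,
    cluster: int,
    cell_subset: Optional[np.ndarray] = None,
    domain: str = "target",
) -> ClusterProfile:
    """Normalized aggregate feature profile of one cluster's cells."""
    members = np.flatnonzero(labels.labels == cluster)
    if cell_subset is not None:
        members = np.intersect1d(members, np.asarray(cell_subset))
    if members.size == 0:
        raise ValueError(f"cluster {cluster} is empty under the given cell subset")
    block = m.values[members]
    vec = np.asarray(block.sum(axis=0)).ravel()
    total = vec.sum()
    if total <= 0:
        raise ValueError(f"cluster {cluster} has zero total signal")
    return ClusterProfile(vec / total, int(cluster), domain, int(members.size))


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence; 0 iff p == q, 1 for disjoint supports."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8 or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("jsd expects probability vectors summing to 1")
    m = 0.5 * (p + q)
    val = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(min(max(val / np.log(2.0), 0.0), 1.0))


def _subsample(rng: np.random.Generator, members: np.ndarray, fraction: float) -> np.ndarray:
    k = max(1, int(np.floor(fraction * members.size)))
    return rng.choice(members, size=k, replace=False)


def _profile_rows(values, members: np.ndarray) -> np.ndarray:
    vec = np.asarray(values[members].sum(axis=0)).ravel()
    s = vec.sum()
    return vec / s if s > 0 else vec


def ajsd(
    source_m: CellFeatureMatrix,
    target_m: CellFeatureMatrix,
    cx: ClusterAssignment,
    cy: ClusterAssignment,
    i: int,
    j: int,
    cfg: MatchConfig,
) -> float:
    """Averaged JSD between source cluster ``i`` and target cluster ``j``.

    Each trial recomputes both profiles from a fresh random subsample
    (``subsample_fraction`` of the cluster's cells, without replacement,
    at least one cell) and the trial JSDs are averaged.
    """
    src = np.flatnonzero(cx.labels == i)
    tgt = np.flatnonzero(cy.labels == j)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("cannot score an empty cluster")
    rng = np.random.default_rng(cfg.seed)
    vals = []
    for _ in range(cfg.n_trials):
        p = _profile_rows(source_m.values, _subsample(rng, src, cfg.subsample_fraction))
        q = _profile_rows(target_m.values, _subsample(rng, tgt, cfg.subsample_fraction))
        if p.sum() <= 0 or q.sum() <= 0:  # all-zero subsample: skip trial
            continue
        vals.append(jsd(p, q))
    return float(np.mean(vals)) if vals else 1.0


def ajsd_matrix(
    source_m: CellFeatureMatrix,
    target_m: CellFeatureMatrix,
    cx: ClusterAssignment,
    cy: ClusterAssignment,
    cfg: MatchConfig,
) -> np.ndarray:
    """(N_s, N_t) AJSD matrix over all source/target cluster pairs.

    Per trial, every cluster is subsampled once and all pairwise JSDs are
    taken from those shared profiles, so a trial probes one consistent
    resampling of the data. Empty clusters score 1 (never matchable below
    any reasonable threshold).
    """
    rng = np.random.default_rng(cfg.seed)
    src_members = [np.flatnonzero(cx.labels == i) for i in range(cx.n_clusters)]
    tgt_members = [np.flatnonzero(cy.labels == j) for j in range(cy.n_clusters)]
    sums = np.zeros((cx.n_clusters, cy.n_clusters))
    counts = np.zeros_like(sums)
    for _ in range(cfg.n_trials):
        p = [
            _profile_rows(source_m.values, _subsample(rng, mem, cfg.subsample_fraction))
            if mem.size
            else None
            for mem in src_members
        ]
        q = [
            _profile_rows(target_m.values, _subsample(rng, mem, cfg.subsample_fraction))
            if mem.size
            else None
            for mem in tgt_members
        ]
        for i, pi in enumerate(p):
            if pi is None or pi.sum() <= 0:
                continue
            for j, qj in enumerate(q):
                if qj is None or qj.sum() <= 0:
                    continue
                sums[i, j] += jsd(pi, qj)
                counts[i, j] += 1
    out = np.ones_like(sums)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def _greedy_pass(D: np.ndarray, target_order: np.ndarray, tau: float) -> List[Tuple[int, int, float]]:
    """Each target cluster, in the given order, claims the closest unmatched
    source cluster, accepted only below the threshold."""
    matches: List[Tuple[int, int, float]] = []
    free = np.ones(D.shape[0], dtype=bool)
    for j in target_order:
        if not free.any():
            break
        col = np.where(free, D[:, j], np.inf)
        i = int(np.argmin(col))
        if col[i] < tau:
            matches.append((i, int(j), float(D[i, j])))
            free[i] = False
    return matches


def match(
    source_m: CellFeatureMatrix,
    target_m: CellFeatureMatrix,
    cx: ClusterAssignment,
    cy: ClusterAssignment,
    cfg: MatchConfig,
    D: Optional[np.ndarray] = None,
) -> MatchResult:
    """Shuffle-minimized exclusive matching of source to target clusters.

    The AJSD matrix is computed once; each of ``n_shuffles`` seeded
    permutations of the target-cluster order yields a greedy exclusive
    assignment, and the configuration minimizing the total AJSD over
    accepted matches wins (ties: more matches, then lower shuffle index).
    An empty match list is a legal outcome — the domains may share no
    populations.
    """
    if D is None:
        D = ajsd_matrix(source_m, target_m, cx, cy, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    best: Optional[List[Tuple[int, int, float]]] = None
    best_total = np.inf
    for r in range(cfg.n_shuffles):
        order = rng.permutation(cy.n_clusters)
        cand = _greedy_pass(D, order, cfg.tau_jsd)
        total = sum(a for _, _, a in cand)
        better = best is None or total < best_total - 1e-12 or (
            abs(total - best_total) <= 1e-12 and len(cand) > len(best)
        )
        if better:
            best, best_total = cand, total
    assert best is not None
    best = sorted(best)
    matched_s = {i for i, _, _ in best}
    matched_t = {j for _, j, _ in best}
    for i, j, a in best:
        logger.info("match: source %d <-> target %d (AJSD=%.4f)", i, j, a)
    for i in range(cx.n_clusters):
        if i not in matched_s:
            logger.info("unmatched source cluster %d (min AJSD=%.4f)", i, float(D[i].min()))
    return MatchResult(
        matches=best,
        unmatched_source=[i for i in range(cx.n_clusters) if i not in matched_s],
        unmatched_target=[j for j in range(cy.n_clusters) if j not in matched_t],
        total_ajsd=float(sum(a for _, _, a in best)),
        ajsd=D,
    )


def exhaustive_best_match(D: np.ndarray, tau: float) -> Tuple[List[Tuple[int, int, float]], float]:
    """Brute-force oracle: minimum-total-AJSD *maximal* valid matching.

    Enumerates all exclusive matchings whose pairs all score below ``tau``
    and that cannot be extended by another valid pair (greedy passes always
    produce maximal matchings). Exponential; intended for <= 6x6 matrices
    in tests only.
    """
    ns, nt = D.shape
    valid = D < tau
    best: List[Tuple[int, int, float]] = []
    best_total = np.inf

    def is_maximal(matched_s: set, matched_t: set) -> bool:
        for i in range(ns):
            if i in matched_s:
                continue
            for j in range(nt):
                if j not in matched_t and valid[i, j]:
                    return False
        return True

    def rec(j: int, matched_s: set, cur: List[Tuple[int, int, float]], total: float):
        nonlocal best, best_total
        if j == nt:
            if is_maximal(matched_s, {t for _, t, _ in cur}) and total < best_total - 1e-15:
                best, best_total = list(cur), total
            return
        rec(j + 1, matched_s, cur, total)  # leave target j unmatched
        for i in range(ns):
            if i not in matched_s and valid[i, j]:
                cur.append((i, j, float(D[i, j])))
                rec(j + 1, matched_s | {i}, cur, total + D[i, j])
                cur.pop()

    rec(0, set(), [], 0.0)
    if not np.isfinite(best_total):
        best_total = 0.0
    return sorted(best), float(best_total)
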