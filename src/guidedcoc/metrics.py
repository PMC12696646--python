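"""External clustering-accuracy metrics: NMI and ARI.

Both are computed from the contingency table of the two labelings.
NMI uses the geometric normalization I(Q;G)/sqrt(H(Q)*H(G)); ARI is the
chance-adjusted Rand index from pair counts. Natural logarithms are used
for the entropies (the base cancels in the ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

__all__ = ["ContingencyTable", "nmi", "ari"]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_totals: np.ndarray
    col_totals: np.ndarray
    n: int

    @classmethod
    def from_labels(cls, Q, G) -> "ContingencyTable":
        Q = np.asarray(Q)
        G = np.asarray(G)
        if Q.shape != G.shape or Q.ndim != 1:
            raise ValueError("labelings must be 1-D and of equal length")
        if Q.size == 0:
            raise ValueError("labelings must be non-empty")
        _, qi = np.unique(Q, return_inverse=True)
        _, gi = np.unique(G, return_inverse=True)
        cq, cg = qi.max() + 1, gi.max() + 1
        counts = np.zeros((cq, cg), dtype=np.int64)
        np.add.at(counts, (qi, gi), 1)
        return cls(counts, counts.sum(axis=1), counts.sum(axis=0), int(Q.size))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(Q, G) -> float:
    """Normalized mutual information, geometric normalization, in [0, 1].

    Degenerate case: if either labeling has zero entropy, returns 1 when
    the two induce the same partition and 0 otherwise.
    """
    t = ContingencyTable.from_labels(Q, G)
    pq = t.row_totals / t.n
    pg = t.col_totals / t.n
    hq, hg = _entropy(pq), _entropy(pg)
    if hq * hg == 0.0:
        same = np.array_equal(
            np.unique(np.asarray(Q), return_inverse=True)[1],
            np.unique(np.asarray(G), return_inverse=True)[1],
        )
        return 1.0 if same else 0.0
    pij = t.counts / t.n
    outer = np.outer(pq, pg)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = float(xlogy(pij, np.where(pij > 0, pij / outer, 1.0)).sum())
    return float(np.clip(mi / np.sqrt(hq * hg), 0.0, 1.0))


def _comb2(x: np.ndarray | int) -> np.ndarray | float:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def ari(Q, G) -> float:
    """Adjusted Rand index in [-1, 1] from the contingency-table pair counts."""
    t = ContingencyTable.from_labels(Q, G)
    sum_ij = _comb2(t.counts).sum()
    sum_q = _comb2(t.row_totals).sum()
    sum_g = _comb2(t.col_totals).sum()
    total = _comb2(t.n)
    if total == 0:
        return 1.0
    expected = sum_q * sum_g / total
    max_index = 0.5 * (sum_q + sum_g)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
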