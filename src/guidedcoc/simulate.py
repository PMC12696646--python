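"""Seeded generator of source/target triples with planted co-cluster blocks.

The generator emulates the structural assumptions of guided co-clustering:
cells belong to planted populations, features to planted modules, and the
expected count of feature ``z`` in cell ``y`` depends only on the
(population, module) block. Shared populations use the *same* block-mean
row in source and target, so their feature profiles agree up to noise;
target-only or source-only populations get private rows. The gene-activity
matrix is a row-paired re-draw of the target cells from block rates
perturbed per (population, module) by a multiplicative log-normal factor
(``atac_distortion``), emulating the noisier, partially concordant ATAC
modality. Counts are Poisson (negative binomial when ``noise > 0``) with
optional zero-inflation (``dropout``) applied after the draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .matrix import CellFeatureMatrix, ClusterAssignment

__all__ = ["SyntheticSpec", "default_block_means", "generate"]


def default_block_means(
    n_pops: int, k_features: int, base: float = 1.0, contrast: float = 3.0
) -> np.ndarray:
    """Cyclic block-mean design: population ``i`` elevates modules
    ``{k : k mod n_pops == i}`` from ``base`` to ``base * contrast``,
    giving every population a distinct elevated-module signature."""
    bm = np.full((n_pops, k_features), base, dtype=float)
    for i in range(n_pops):
        bm[i, np.arange(k_features) % n_pops == i] = base * contrast
    return bm


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic source/target triple.

    Defaults describe a mid-sized, realistically sparse setting: five
    populations shared between domains, twelve feature modules, 3x
    between-block contrast, 70% dropout, and a moderately distorted ATAC
    modality. ``target_dropout``/``target_noise`` override the shared
    values on the target matrices for clean-source/noisy-target scenarios.
    """

    n_source: int = 500
    n_target: int = 800
    q: int = 400
    n_source_clusters: int = 5
    n_target_clusters: int = 5
    k_features: int = 12
    shared_populations: Optional[List[Tuple[int, int]]] = None  # None -> (i, i) for all
    block_means: Optional[np.ndarray] = None  # (n_pops, K); None -> default design
    noise: float = 0.0  # NB inverse-dispersion scale; 0 -> Poisson
    dropout: float = 0.7
    atac_distortion: float = 0.5
    target_dropout: Optional[float] = None
    target_noise: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_populations is None:
            m = min(self.n_source_clusters, self.n_target_clusters)
            self.shared_populations = [(i, i) for i in range(m)]
        src = [s for s, _ in self.shared_populations]
        tgt = [t for _, t in self.shared_populations]
        if len(set(src)) != len(src) or len(set(tgt)) != len(tgt):
            raise ValueError("shared_populations must be exclusive per side")
        if any(s >= self.n_source_clusters or t >= self.n_target_clusters for s, t in self.shared_populations):
            raise ValueError("shared_populations index out of range")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.noise < 0 or self.atac_distortion < 0:
            raise ValueError("noise and atac_distortion must be >= 0")
        n_pops = self.n_source_clusters + self.n_target_clusters - len(self.shared_populations)
        if self.block_means is None:
            self.block_means = default_block_means(n_pops, self.k_features)
        self.block_means = np.asarray(self.block_means, dtype=float)
        if self.block_means.shape != (n_pops, self.k_features):
            raise ValueError(
                f"block_means must have shape ({n_pops}, {self.k_features}) "
                "(one row per distinct population)"
            )
        if np.any(self.block_means <= 0):
            raise ValueError("block rates must be positive")

    def population_rows(self) -> Tuple[np.ndarray, np.ndarray]:
        """Map (source cluster, target cluster) -> block_means row index.

        Source cluster ``i`` uses row ``i``; a shared target cluster reuses
        its source partner's row; target-only clusters take fresh rows."""
        src_rows = np.arange(self.n_source_clusters)
        tgt_rows = np.full(self.n_target_clusters, -1)
        for s, t in self.shared_populations:
            tgt_rows[t] = s
        nxt = self.n_source_clusters
        for t in range(self.n_target_clusters):
            if tgt_rows[t] < 0:
                tgt_rows[t] = nxt
                nxt += 1
        return src_rows, tgt_rows


def _even_labels(n: int, k: int) -> np.ndarray:
    """Contiguous near-even split of n items into k clusters."""
    return (np.arange(n) * k) // n


def _draw_counts(rng: np.random.Generator, rates: np.ndarray, noise: float, dropout: float) -> np.ndarray:
    if noise > 0:
        shape = 1.0 / noise
        lam = rng.gamma(shape, rates * noise)
    else:
        lam = rates
    counts = rng.poisson(lam).astype(float)
    if dropout > 0:
        counts[rng.random(counts.shape) < dropout] = 0.0
    return counts


def generate(spec: SyntheticSpec):
    """Draw one (R_s, R_t, A_t, cx, planted_cy, planted_cz) instance.

    Deterministic given ``spec.seed``. Feature modules are contiguous
    blocks of near-equal size; cells are split near-evenly across clusters.
    """
    rng = np.random.default_rng(spec.seed)
    cx_lab = _even_labels(spec.n_source, spec.n_source_clusters)
    cy_lab = _even_labels(spec.n_target, spec.n_target_clusters)
    cz_lab = _even_labels(spec.q, spec.k_features)
    src_rows, tgt_rows = spec.population_rows()

    def cell_rates(labels: np.ndarray, rows: np.ndarray, bm: np.ndarray) -> np.ndarray:
        return bm[rows[labels]][:, cz_lab]

    t_drop = spec.dropout if spec.target_dropout is None else spec.target_dropout
    t_noise = spec.noise if spec.target_noise is None else spec.target_noise

    R_s = _draw_counts(rng, cell_rates(cx_lab, src_rows, spec.block_means), spec.noise, spec.dropout)
    R_t = _draw_counts(rng, cell_rates(cy_lab, tgt_rows, spec.block_means), t_noise, t_drop)
    # ATAC modality: same planted cell clusters, block rates jittered per
    # (population, module); the log-normal factor is mean-one so the
    # expected library size is preserved.
    sig = spec.atac_distortion
    factor = np.exp(rng.normal(0.0, sig, size=spec.block_means.shape) - 0.5 * sig**2)
    A_t = _draw_counts(rng, cell_rates(cy_lab, tgt_rows, spec.block_means * factor), t_noise, t_drop)

    mats = []
    for vals, prefix, fid in ((R_s, "src", True), (R_t, "tgt", True), (A_t, "tgt", False)):
        cells = np.array([f"{prefix}_{i:05d}" for i in range(vals.shape[0])], dtype=object)
        feats = np.array([f"g{j:05d}" for j in range(spec.q)], dtype=object)
        mats.append(CellFeatureMatrix(vals, cells, feats))
    R_s_m, R_t_m, A_t_m = mats
    return (
        R_s_m,
        R_t_m,
        A_t_m,
        ClusterAssignment(cx_lab, spec.n_source_clusters),
        ClusterAssignment(cy_lab, spec.n_target_clusters),
        ClusterAssignment(cz_lab, spec.k_features),
    )
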