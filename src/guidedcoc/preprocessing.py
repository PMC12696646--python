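"""Feature selection, normalization, gene-activity scores, feature alignment.

The pipeline selects highly variable genes (HVGs) on the *source* RNA
matrix, applies the same gene set to the target RNA and gene-activity
matrices (through a homolog table for cross-species runs, one-to-one
orthologs only), and log2(x+1)-transforms all values. Gene-activity scores
summarize scATAC-seq signal per gene by summing peak counts over the gene
body plus a 2-kb upstream promoter window, strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CellFeatureMatrix

__all__ = [
    "GeneAnnotation",
    "PeakMatrix",
    "select_hvgs",
    "log_normalize",
    "gene_activity",
    "align_features",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """One gene locus, 0-based half-open coordinates (BED convention)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    def extended(self, promoter_bp: int) -> Tuple[int, int]:
        """Gene body plus the upstream promoter window, clipped at 0."""
        if self.strand == "+":
            return max(0, self.start - promoter_bp), self.end
        return self.start, self.end + promoter_bp


@dataclass
class PeakMatrix:
    """Cell x peak accessibility counts with peak intervals (0-based half-open)."""

    values: np.ndarray | sp.spmatrix
    peaks: List[Tuple[str, int, int]]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.peaks):
            raise ValueError("one interval required per peak column")
        for chrom, s, e in self.peaks:
            if s >= e:
                raise ValueError(f"invalid peak interval {chrom}:{s}-{e}")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("one id required per cell row")


def _feature_moments(m: CellFeatureMatrix) -> Tuple[np.ndarray, np.ndarray]:
    v = m.values
    # all-zero cells carry no dispersion information; dropping them makes
    # the ranking invariant to padding with empty cells
    cell_tot = np.asarray(v.sum(axis=1)).ravel()
    if (cell_tot == 0).any():
        v = v[cell_tot > 0]
    n = v.shape[0]
    if sp.issparse(v):
        mean = np.asarray(v.mean(axis=0)).ravel()
        sq = np.asarray(v.multiply(v).mean(axis=0)).ravel()
    else:
        mean = v.mean(axis=0)
        sq = (v**2).mean(axis=0)
    var = (sq - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvgs(source: CellFeatureMatrix, n_top: int = 2500, n_bins: int = 20) -> List[str]:
    """Rank features by binned, z-scored dispersion and keep the top ``n_top``.

    Dispersion is the variance-to-mean ratio; features are grouped into
    ``n_bins`` equal-count bins of mean expression and the dispersion is
    z-scored within each bin, so highly expressed genes do not dominate.
    Constant (zero-variance) features are never ranked above varying ones.
    """
    mean, var = _feature_moments(source)
    usable = var > 0
    n_usable = int(usable.sum())
    if n_usable < n_top:
        logger.warning("only %d features with positive variance (requested %d)", n_usable, n_top)
    idx = np.flatnonzero(usable)
    disp = np.zeros_like(mean)
    disp[idx] = var[idx] / np.where(mean[idx] > 0, mean[idx], 1.0)
    z = np.full(len(mean), -np.inf)
    if idx.size:
        bins = pd.qcut(mean[idx], q=min(n_bins, idx.size), labels=False, duplicates="drop")
        df = pd.DataFrame({"bin": bins, "disp": disp[idx]})
        grp = df.groupby("bin")["disp"]
        mu = grp.transform("mean").to_numpy()
        sd = grp.transform("std").fillna(0.0).to_numpy()
        zi = np.where(sd > 0, (disp[idx] - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        z[idx] = zi
    order = np.argsort(-z, kind="stable")
    order = order[np.isfinite(z[order])]
    top = order[: min(n_top, order.size)]
    return [str(g) for g in source.feature_ids[top]]


def log_normalize(m: CellFeatureMatrix) -> CellFeatureMatrix:
    """Elementwise log2(x+1); refuses to run twice on the same matrix."""
    if m.transform == "log2p1":
        raise ValueError("matrix is already log2(x+1)-transformed")
    if sp.issparse(m.values):
        out = m.values.copy().tocsr()
        out.data = np.log2(out.data + 1.0)
    else:
        out = np.log2(m.values + 1.0)
    return CellFeatureMatrix(out, m.cell_ids.copy(), m.feature_ids.copy(), transform="log2p1")


def gene_activity(
    pm: PeakMatrix, genes: Sequence[GeneAnnotation], promoter_bp: int = 2000
) -> CellFeatureMatrix:
    """Per-cell, per-gene accessibility from a peak matrix.

    A peak contributes its counts to every gene whose extended interval
    (gene body + ``promoter_bp`` upstream of the TSS) it overlaps by at
    least one base (half-open semantics). Scores are log2(x+1)-transformed.
    """
    chroms = {}
    for p_idx, (chrom, s, e) in enumerate(pm.peaks):
        chroms.setdefault(chrom, []).append((p_idx, s, e))
    n_cells = pm.values.shape[0]
    indicator = sp.lil_matrix((len(pm.peaks), len(genes)))
    for g_idx, g in enumerate(genes):
        if g.chrom not in chroms:
            logger.warning("gene %s on unknown chromosome %s: scored 0", g.gene_id, g.chrom)
            continue
        gs, ge = g.extended(promoter_bp)
        for p_idx, ps, pe in chroms[g.chrom]:
            if ps < ge and pe > gs:
                indicator[p_idx, g_idx] = 1.0
    scores = pm.values @ indicator.tocsr()
    if sp.issparse(scores):
        scores = scores.tocsr()
        scores.data = np.log2(scores.data + 1.0)
    else:
        scores = np.log2(np.asarray(scores) + 1.0)
    gene_ids = np.array([g.gene_id for g in genes], dtype=object)
    return CellFeatureMatrix(scores, pm.cell_ids.copy(), gene_ids, transform="log2p1")


def _one_to_one(homolog_map: pd.DataFrame) -> dict:
    """Source->target gene map restricted to one-to-one pairs."""
    df = homolog_map.iloc[:, :2].copy()
    df.columns = ["source", "target"]
    df = df.drop_duplicates()
    src_counts = df["source"].value_counts()
    tgt_counts = df["target"].value_counts()
    keep = df[(df["source"].map(src_counts) == 1) & (df["target"].map(tgt_counts) == 1)]
    return dict(zip(keep["source"], keep["target"]))


def align_features(
    source: CellFeatureMatrix,
    target_rna: CellFeatureMatrix,
    target_activity: CellFeatureMatrix,
    hvgs: Sequence[str],
    homolog_map: Optional[pd.DataFrame] = None,
) -> Tuple[CellFeatureMatrix, CellFeatureMatrix, CellFeatureMatrix]:
    """Subset all three matrices to a common, identically ordered gene set.

    The HVG list (source vocabulary) is intersected with the target
    vocabulary — through the homolog table when given, one-to-one pairs
    only — and columns are ordered identically; target columns are renamed
    to source gene ids so downstream code sees one vocabulary. Genes with
    zero total signal in any matrix are dropped and reported.
    """
    if not np.array_equal(target_rna.feature_ids, target_activity.feature_ids):
        raise ValueError("target RNA and activity matrices must share feature ids")
    mapping = _one_to_one(homolog_map) if homolog_map is not None else None
    tgt_index = {g: i for i, g in enumerate(target_rna.feature_ids)}
    src_index = {g: i for i, g in enumerate(source.feature_ids)}
    kept_src, kept_tgt = [], []
    for g in hvgs:
        if g not in src_index:
            raise ValueError(f"HVG {g!r} not present in the source matrix")
        t = mapping.get(g) if mapping is not None else g
        if t is not None and t in tgt_index:
            kept_src.append(src_index[g])
            kept_tgt.append(tgt_index[t])
    if not kept_src:
        raise ValueError("no HVGs could be mapped into the target feature space")
    names = source.feature_ids[np.asarray(kept_src)]
    s = source.subset_features(np.asarray(kept_src), names)
    r = target_rna.subset_features(np.asarray(kept_tgt), names)
    a = target_activity.subset_features(np.asarray(kept_tgt), names)

    def _colsum(m):
        return np.asarray(m.values.sum(axis=0)).ravel()

    nonzero = (_colsum(s) > 0) & (_colsum(r) > 0) & (_colsum(a) > 0)
    dropped = [str(g) for g in names[~nonzero]]
    if dropped:
        logger.warning("dropping %d all-zero genes after alignment: %s",
                       len(dropped), ", ".join(dropped[:10]))
    keep_idx = np.flatnonzero(nonzero)
    if keep_idx.size == 0:
        raise ValueError("feature alignment left no gene with signal in all matrices")
    return (
        s.subset_features(keep_idx),
        r.subset_features(keep_idx),
        a.subset_features(keep_idx),
    )
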