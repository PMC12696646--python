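"""End-to-end orchestration: preprocess -> Stage-1 fit -> Stage-2 match.

``run_pipeline`` reads the three matrices (or a peak matrix plus gene
annotations in place of the activity matrix), aligns features to the
source HVGs, log-transforms, runs both stages and writes: cell labels,
feature labels, the objective trace, the match table, and a JSON manifest
of hyperparameters/seed/versions sufficient to reproduce every artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    read_gene_annotations,
    read_homolog_map,
    read_labels,
    read_matrix,
    write_labels,
    write_manifest,
)
from .matrix import CellFeatureMatrix
from .metrics import ari, nmi
from .preprocessing import PeakMatrix, align_features, gene_activity, log_normalize, select_hvgs
from .stage1 import Stage1Config, fit
from .stage2 import MatchConfig, match

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ValidationError", "run_pipeline"]


class ValidationError(ValueError):
    """Bad or mutually inconsistent inputs (CLI exit code 2)."""


@dataclass
class RunConfig:
    source_path: str
    target_rna_path: str
    cx_path: str
    target_activity_path: Optional[str] = None
    peak_matrix_path: Optional[str] = None
    annotations_path: Optional[str] = None
    homolog_map_path: Optional[str] = None
    ground_truth_path: Optional[str] = None
    n_hvgs: int = 2500
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: MatchConfig = field(default_factory=MatchConfig)
    out_dir: str = "guidedcoc_out"

    def __post_init__(self) -> None:
        has_activity = self.target_activity_path is not None
        has_peaks = self.peak_matrix_path is not None and self.annotations_path is not None
        if has_activity == has_peaks:
            raise ValidationError(
                "provide exactly one of: an activity matrix, or a peak matrix plus gene annotations"
            )


def _load(path: str, what: str) -> CellFeatureMatrix:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"{what}: file not found: {path}")
    return read_matrix(p)


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    R_s = _load(cfg.source_path, "source matrix (R_s)")
    R_t = _load(cfg.target_rna_path, "target RNA matrix (R_t)")
    if not Path(cfg.cx_path).exists():
        raise ValidationError(f"source labels (cx): file not found: {cfg.cx_path}")
    cx_ids, cx = read_labels(cfg.cx_path)
    if len(cx_ids) != R_s.n_cells or not np.array_equal(cx_ids, R_s.cell_ids):
        raise ValidationError("source labels (cx) do not match the source matrix cell ids")

    if cfg.target_activity_path is not None:
        A_t = _load(cfg.target_activity_path, "target activity matrix (A_t)")
        if A_t.transform is None:
            A_t = log_normalize(A_t)
    else:
        pm_raw = _load(cfg.peak_matrix_path, "peak matrix")
        peaks = []
        for pid in pm_raw.feature_ids:
            try:
                chrom, span = str(pid).split(":")
                s, e = span.split("-")
                peaks.append((chrom, int(s), int(e)))
            except ValueError as exc:
                raise ValidationError(f"peak id {pid!r} is not of the form chrom:start-end") from exc
        pm = PeakMatrix(pm_raw.values, peaks, pm_raw.cell_ids)
        genes = read_gene_annotations(cfg.annotations_path)
        A_t = gene_activity(pm, genes)
    if not np.array_equal(R_t.cell_ids, A_t.cell_ids):
        raise ValidationError("target RNA and activity matrices are not row-paired")

    homolog = read_homolog_map(cfg.homolog_map_path) if cfg.homolog_map_path else None
    hvgs = select_hvgs(R_s, n_top=cfg.n_hvgs)
    R_s_a, R_t_a, A_t_a = align_features(R_s, R_t, A_t, hvgs, homolog_map=homolog)
    R_s_n = log_normalize(R_s_a) if R_s_a.transform is None else R_s_a
    R_t_n = log_normalize(R_t_a) if R_t_a.transform is None else R_t_a

    result = fit(R_t_n, A_t_a, R_s_n, cx, cfg.stage1)
    write_labels(R_t_n.cell_ids, result.state.cy, out / "cell_clusters.tsv")
    write_labels(R_t_n.feature_ids, result.state.cz, out / "feature_clusters.tsv",
                 id_col="feature_id", label_col="feature_cluster")
    pd.DataFrame(
        {"iteration": np.arange(1, len(result.objective_trace) + 1),
         "objective": result.objective_trace}
    ).to_csv(out / "objective_trace.csv", index=False)

    mres = match(R_s_n, R_t_n, cx, result.state.cy, cfg.stage2)
    rows = [
        {"source_cluster": i, "target_cluster": j, "ajsd": a, "matched": True}
        for i, j, a in mres.matches
    ]
    rows += [
        {"source_cluster": i, "target_cluster": -1,
         "ajsd": float(mres.ajsd[i].min()), "matched": False}
        for i in mres.unmatched_source
    ]
    pd.DataFrame(rows, columns=["source_cluster", "target_cluster", "ajsd", "matched"]).to_csv(
        out / "matches.tsv", sep="\t", index=False
    )

    report = {
        "version": __version__,
        "n_hvgs": cfg.n_hvgs,
        "n_genes_aligned": int(R_t_n.n_features),
        "stage1": {
            "n_target_clusters": cfg.stage1.n_target_clusters,
            "k_features": cfg.stage1.k_features,
            "alpha": cfg.stage1.alpha,
            "beta": cfg.stage1.beta,
            "max_iter": cfg.stage1.max_iter,
            "tol": cfg.stage1.tol,
            "seed": cfg.stage1.seed,
            "init_method": cfg.stage1.init_method,
            "n_iter": result.n_iter,
            "converged": result.converged,
            "final_objective": result.objective_trace[-1] if result.objective_trace else None,
        },
        "stage2": {
            "n_trials": cfg.stage2.n_trials,
            "n_shuffles": cfg.stage2.n_shuffles,
            "tau_jsd": cfg.stage2.tau_jsd,
            "subsample_fraction": cfg.stage2.subsample_fraction,
            "seed": cfg.stage2.seed,
            "n_matches": len(mres.matches),
            "total_ajsd": mres.total_ajsd,
        },
        "inputs": {
            "source": cfg.source_path,
            "target_rna": cfg.target_rna_path,
            "target_activity": cfg.target_activity_path,
            "peak_matrix": cfg.peak_matrix_path,
            "annotations": cfg.annotations_path,
            "cx": cfg.cx_path,
        },
    }
    if cfg.ground_truth_path:
        gt_ids, gt = read_labels(cfg.ground_truth_path)
        if not np.array_equal(gt_ids, R_t_n.cell_ids):
            raise ValidationError("ground-truth labels do not match target cell ids")
        report["evaluation"] = {
            "nmi": nmi(result.state.cy.labels, gt.labels),
            "ari": ari(result.state.cy.labels, gt.labels),
        }
        logger.info("evaluation vs ground truth: NMI=%.4f ARI=%.4f",
                    report["evaluation"]["nmi"], report["evaluation"]["ari"])
    write_manifest(out / "manifest.json", report)
    return report
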