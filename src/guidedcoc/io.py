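"""Readers and writers for the on-disk formats the CLI speaks.

Matrices travel either as MatrixMarket (``.mtx``) files with sidecar
row/column name files (one id per line: ``<stem>.rownames.txt`` /
``<stem>.colnames.txt``) or as dense TSV with cell ids in the index and
feature ids in the header. Labels are two-column TSVs. Gene annotations
are BED6 (0-based half-open) or GTF (1-based closed, converted on read).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CellFeatureMatrix, ClusterAssignment
from .preprocessing import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_gene_annotations",
    "read_homolog_map",
]


def _names_path(mtx: Path, which: str) -> Path:
    return mtx.with_suffix("").with_suffix(f".{which}.txt") if mtx.suffix == ".mtx" else mtx


def read_matrix(path: str | Path) -> CellFeatureMatrix:
    """Load a cells x features matrix from ``.mtx`` (+ name sidecars) or TSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        values = sp.csr_matrix(scipy.io.mmread(str(path)))
        stem = path.with_suffix("")
        rows = Path(f"{stem}.rownames.txt").read_text().split()
        cols = Path(f"{stem}.colnames.txt").read_text().split()
        m = CellFeatureMatrix(values, np.asarray(rows, dtype=object), np.asarray(cols, dtype=object))
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        m = CellFeatureMatrix(
            df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    logger.info("read %s: %d cells x %d features", path, m.n_cells, m.n_features)
    return m


def write_matrix(m: CellFeatureMatrix, path: str | Path) -> None:
    """Write as MatrixMarket + name sidecars (``.mtx``) or dense TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".mtx":
        vals = m.values if sp.issparse(m.values) else sp.coo_matrix(m.values)
        scipy.io.mmwrite(str(path), vals)
        stem = path.with_suffix("")
        Path(f"{stem}.rownames.txt").write_text("\n".join(map(str, m.cell_ids)) + "\n")
        Path(f"{stem}.colnames.txt").write_text("\n".join(map(str, m.feature_ids)) + "\n")
    else:
        pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.feature_ids).to_csv(path, sep="\t")


def read_labels(path: str | Path) -> Tuple[np.ndarray, ClusterAssignment]:
    """Two-column TSV (item id, cluster) -> (ids, assignment).

    Cluster values may be arbitrary strings; they are factorized into
    0..c-1 in order of first appearance.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, cluster)")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    codes, uniques = pd.factorize(df.iloc[:, 1])
    return ids, ClusterAssignment(codes, len(uniques))


def write_labels(ids: np.ndarray, labels: ClusterAssignment, path: str | Path,
                 id_col: str = "cell_id", label_col: str = "cluster") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({id_col: ids, label_col: labels.labels}).to_csv(path, sep="\t", index=False)


def read_gene_annotations(path: str | Path) -> List[GeneAnnotation]:
    """BED6 (``.bed``) or GTF/GFF gene records -> annotations.

    GTF coordinates (1-based, closed) are converted to 0-based half-open;
    only ``gene`` feature lines are used, with ``gene_id`` from column 9.
    """
    path = Path(path)
    out: List[GeneAnnotation] = []
    if path.suffix == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GeneAnnotation(f[3], f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+"))
    else:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].rstrip(";").split(";") if " " in kv.strip()
            )
            gid = attrs.get("gene_id", f"gene{len(out)}").strip('"')
            out.append(GeneAnnotation(gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    if not out:
        raise ValueError(f"{path}: no gene records found")
    return out


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (source gene, target gene)")
    return df


def write_manifest(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
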