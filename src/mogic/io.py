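"""Readers and writers for the on-disk formats.

Matrices travel as MatrixMarket ``.mtx`` with ``<stem>.barcodes.tsv`` /
``<stem>.features.tsv`` sidecars (one id per line), or as dense CSV with the
first column holding cell ids and the header holding feature ids.  Labels are
a two-column CSV ``cell_id,cell_type``.  Gene annotations are 5-column TSV;
peaks are BED (3+ columns).
"""

from __future__ import annotations

import csv
import os
import warnings
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CellFeatureMatrix, EmbeddingSet, GeneAnnotation, PeakMatrix


def _read_ids(path: str, what: str) -> List[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing {what} sidecar: {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return ids


def read_matrix(path: str, modality: str = "RNA",
                format_hint: Optional[str] = None) -> CellFeatureMatrix:
    """Read a cells x features matrix (MatrixMarket + sidecars, or dense CSV).

    Format is auto-detected from the extension unless ``format_hint`` is
    'mtx' or 'csv'.  Ids are validated for uniqueness.
    """
    fmt = format_hint
    if fmt is None:
        fmt = "mtx" if path.endswith(".mtx") else "csv"
    if fmt == "mtx":
        try:
            values = mmread(path)
        except Exception as exc:
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        stem = path[:-4]
        cells = _read_ids(stem + ".barcodes.tsv", "barcodes")
        feats = _read_ids(stem + ".features.tsv", "features")
        values = sp.csr_matrix(values)
    elif fmt == "csv":
        with open(path) as fh:  # pandas mangles duplicate columns, so check raw
            header = fh.readline().rstrip("\n").split(",")[1:]
        seen = set()
        for col in header:
            if col in seen:
                raise ValueError(f"duplicate feature id in CSV header: {col!r}")
            seen.add(col)
        df = pd.read_csv(path, index_col=0)
        cells = [str(c) for c in df.index]
        feats = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=np.float64)
    else:
        raise ValueError(f"unknown format hint {fmt!r}")
    m = CellFeatureMatrix(values, cells, feats, modality)
    nnz = values.nnz if sp.issparse(values) else int(np.count_nonzero(values))
    warnings.warn(f"read {path}: {m.n_cells} x {m.n_features}, nnz={nnz}", UserWarning)
    return m


def write_matrix(m: CellFeatureMatrix, path: str, fmt: str = "mtx") -> None:
    if fmt == "mtx":
        if not path.endswith(".mtx"):
            path = path + ".mtx"
        mmwrite(path, sp.csr_matrix(m.values))
        stem = path[:-4]
        with open(stem + ".barcodes.tsv", "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
        with open(stem + ".features.tsv", "w") as fh:
            fh.write("\n".join(m.feature_ids) + "\n")
    elif fmt == "csv":
        pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.feature_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path: str) -> Tuple[List[str], List[str]]:
    """Labels CSV with header ``cell_id,cell_type`` -> (cell_ids, labels)."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["cell_id", "cell_type"]:
        raise ValueError(f"{path}: expected header 'cell_id,cell_type'")
    return [str(c) for c in df["cell_id"]], [str(l) for l in df["cell_type"]]


def write_labels(cell_ids: List[str], labels: List[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id,cell_type\n")
        for c, l in zip(cell_ids, labels):
            fh.write(f"{c},{l}\n")


def read_bed_peaks(path: str) -> List[Tuple[str, int, int]]:
    """BED (3+ columns, 0-based half-open) -> list of (chrom, start, end)."""
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 columns")
            peaks.append((parts[0], int(parts[1]), int(parts[2])))
    return peaks


def read_gene_annotation(path: str) -> GeneAnnotation:
    """TSV ``gene_id  chrom  start  end  strand`` (header optional)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":  # header
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: annotation line needs 5 columns")
            rows.append((parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4]))
    if not rows:
        raise ValueError(f"{path}: empty gene annotation")
    return GeneAnnotation(
        gene_ids=[r[0] for r in rows], chroms=[r[1] for r in rows],
        starts=np.array([r[2] for r in rows]), ends=np.array([r[3] for r in rows]),
        strands=[r[4] for r in rows],
    )


def write_embeddings(es: EmbeddingSet, path: str) -> None:
    """CSV export with header ``cell_id,modality,dim_0..dim_{o-1}``."""
    d = es.Z_R.shape[1]
    header = ["cell_id", "modality"] + [f"dim_{i}" for i in range(d)]
    joint = es.joint
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for cid, mod, row in zip(es.joint_cell_ids, es.joint_modality, joint):
            w.writerow([cid, mod] + [repr(float(v)) for v in row])


def read_embeddings(path: str) -> EmbeddingSet:
    df = pd.read_csv(path)
    dims = [c for c in df.columns if c.startswith("dim_")]
    rna = df[df["modality"] == "RNA"]
    atac = df[df["modality"] == "ATAC"]
    return EmbeddingSet(
        Z_R=rna[dims].to_numpy(), Z_A=atac[dims].to_numpy(),
        cell_ids=[str(c) for c in rna["cell_id"]],
    )
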