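"""Preprocessing: gene-activity scoring, normalization, HVG, scaling, PCA.

The pipeline mirrors standard single-cell practice: library-size
normalization to ``target_sum`` followed by log1p, highly-variable-gene
selection, per-feature standardization with clipping, and exact-SVD PCA.
ATAC peak counts are optionally collapsed to a gene-activity matrix by
summing peak counts over each gene body extended upstream of the TSS
(strand-aware).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import svd

from .containers import CellFeatureMatrix, GeneAnnotation, PeakMatrix


@dataclass
class PreprocConfig:
    target_sum: float = 1e4
    n_hvg: int = 2000
    n_pca: int = 30
    scale_clip: float = 10.0
    promoter_upstream_bp: int = 2000

    def __post_init__(self) -> None:
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.n_hvg < 1 or self.n_pca < 1:
            raise ValueError("n_hvg and n_pca must be positive")
        if self.n_pca > self.n_hvg:
            raise ValueError("n_pca must not exceed n_hvg")
        if self.scale_clip <= 0:
            raise ValueError("scale_clip must be positive")
        if self.promoter_upstream_bp < 0:
            raise ValueError("promoter_upstream_bp must be non-negative")


def peaks_to_gene_activity(
    pm: PeakMatrix, ann: GeneAnnotation, cfg: PreprocConfig = PreprocConfig()
) -> CellFeatureMatrix:
    """Sum peak counts over each gene's body extended upstream of its TSS.

    For a '+' gene the scored window is [start - upstream, end); for a '-'
    gene it is [start, end + upstream); windows are clipped at 0.  A peak
    overlapping several genes counts toward each.  Genes without any
    overlapping peak keep an all-zero column.
    """
    if len(ann) == 0:
        raise ValueError("empty gene annotation")
    up = cfg.promoter_upstream_bp
    g_start = np.where(np.array(ann.strands) == "+", ann.starts - up, ann.starts)
    g_end = np.where(np.array(ann.strands) == "+", ann.ends, ann.ends + up)
    g_start = np.clip(g_start, 0, None)

    vals = sp.csc_matrix(pm.values) if sp.issparse(pm.values) else np.asarray(pm.values)
    n_cells, n_genes = len(pm.cell_ids), len(ann)
    out = np.zeros((n_cells, n_genes), dtype=np.float64)

    p_chrom = np.array([p[0] for p in pm.peaks])
    p_start = np.array([p[1] for p in pm.peaks], dtype=np.int64)
    p_end = np.array([p[2] for p in pm.peaks], dtype=np.int64)

    if not set(p_chrom) & set(ann.chroms):
        warnings.warn("no shared chromosomes between peaks and annotation; all-zero matrix")

    ann_chroms = np.array(ann.chroms)
    for j in range(n_genes):
        on_chrom = p_chrom == ann_chroms[j]
        # half-open overlap: peak.start < gene_end and peak.end > gene_start
        hits = np.flatnonzero(on_chrom & (p_start < g_end[j]) & (p_end > g_start[j]))
        if hits.size:
            if sp.issparse(vals):
                out[:, j] = np.asarray(vals[:, hits].sum(axis=1)).ravel()
            else:
                out[:, j] = vals[:, hits].sum(axis=1)

    return CellFeatureMatrix(out, list(pm.cell_ids), list(ann.gene_ids), "ATAC")


def normalize_log(m: CellFeatureMatrix, cfg: PreprocConfig = PreprocConfig()) -> CellFeatureMatrix:
    """Scale each cell to row-sum ``target_sum``, then ln(1+x).

    Cells with zero total are left as all-zero rows (with a warning).
    """
    x = m.dense().astype(np.float64)
    if x.size and x.min() < 0:
        raise ValueError("normalize_log requires non-negative values")
    row_sums = x.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total count left as zeros")
    scale = np.where(zero, 1.0, cfg.target_sum / np.where(zero, 1.0, row_sums))
    return m.copy_with(values=np.log1p(x * scale[:, None]))


def select_hvg(m: CellFeatureMatrix, n_hvg: int) -> CellFeatureMatrix:
    """Keep the ``n_hvg`` features with highest variance of the (log) values.

    Output feature order is descending variance, ties broken by feature id.
    If ``n_hvg`` exceeds the feature count all features are kept (warning).
    """
    x = m.dense()
    if n_hvg > m.n_features:
        warnings.warn(f"n_hvg={n_hvg} > {m.n_features} features; keeping all")
        n_hvg = m.n_features
    var = x.var(axis=0)  # population (n) denominator
    ids = np.array(m.feature_ids)
    order = np.lexsort((ids, -var))  # primary: descending variance; ties: id ascending
    keep = order[:n_hvg]
    return m.copy_with(values=x[:, keep], feature_ids=ids[keep].tolist())


def scale_features(m: CellFeatureMatrix, scale_clip: float = 10.0) -> CellFeatureMatrix:
    """Standardize each feature to zero mean / unit variance (n denominator),
    then clip to [-scale_clip, +scale_clip].  Zero-variance features become 0."""
    x = m.dense().astype(np.float64)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population convention
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd_safe
    z[:, sd == 0] = 0.0
    return m.copy_with(values=np.clip(z, -scale_clip, scale_clip))


def reduce_pca(m: CellFeatureMatrix, n_pca: int) -> CellFeatureMatrix:
    """Project onto the top ``n_pca`` principal components via exact SVD.

    Deterministic sign convention: each component is flipped so that its
    largest-|loading| entry is positive.
    """
    x = m.dense().astype(np.float64)
    if n_pca > min(x.shape):
        raise ValueError(f"n_pca={n_pca} exceeds min(n_cells, n_features)={min(x.shape)}")
    xc = x - x.mean(axis=0)
    u, s, vt = svd(xc, full_matrices=False)
    u, s, vt = u[:, :n_pca], s[:n_pca], vt[:n_pca]
    flip = np.sign(vt[np.arange(n_pca), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = (u * s) * flip
    return m.copy_with(values=scores, feature_ids=[f"PC{i + 1}" for i in range(n_pca)])


def preprocess_matrix(m: CellFeatureMatrix, cfg: PreprocConfig) -> CellFeatureMatrix:
    """normalize_log -> select_hvg -> scale_features -> reduce_pca."""
    out = normalize_log(m, cfg)
    out = select_hvg(out, cfg.n_hvg)
    out = scale_features(out, cfg.scale_clip)
    n_pca = min(cfg.n_pca, min(out.values.shape))
    if n_pca < cfg.n_pca:
        warnings.warn(f"n_pca reduced to {n_pca} to fit the data")
    return reduce_pca(out, n_pca)
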