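"""Synthetic paired RNA/ATAC data with known cell types.

The generator emulates the assumption underlying paired multi-omics
integration: cell *i* in the RNA matrix and cell *i* in the ATAC matrix are
the same physical cell, so both observations derive from one shared latent
state.  The model:

1. cell-type labels allocated from ``type_proportions`` (largest-remainder
   rounding, so every type is guaranteed its proportional share, then a
   seeded permutation assigns them to cells);
2. one unit-norm Gaussian centroid per type in ``latent_dim`` dimensions;
   per-cell latent = centroid + isotropic Gaussian jitter (sd 0.1);
3. RNA mean = softplus(loading @ latent) rescaled per cell to a fixed
   library size; counts drawn negative-binomially (gamma-Poisson) with
   shape ``rna_dispersion``;
4. ATAC gene-activity value = log1p(RNA mean) + N(0, atac_noise_sd),
   clipped at zero, then zeroed with probability ``atac_dropout``.

Marker genes for a type get their loading row boosted along that type's
centroid direction, giving elevated means in the assigned type in *both*
modalities.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .containers import CellFeatureMatrix

# Fixed world constants (see docs/methods.md for rationale).
LIBRARY_SIZE = 2000.0
LATENT_JITTER_SD = 0.1


@dataclass
class SimConfig:
    """Parameters of the paired-data generator.

    Defaults describe a balanced 3-type, 600-cell, 200-gene dataset with
    moderate ATAC noise — small enough to run end to end in seconds yet
    structured enough that integration is learnable.
    """

    n_cells: int = 600
    n_types: int = 3
    type_proportions: Optional[Sequence[float]] = None
    n_genes: int = 200
    n_markers_per_type: int = 10
    latent_dim: int = 10
    rna_dispersion: float = 2.0
    atac_noise_sd: float = 0.3
    atac_dropout: float = 0.02
    rare_type_fraction: Optional[float] = None
    marker_strength: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_types", "n_genes", "latent_dim"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_markers_per_type < 0:
            raise ValueError("n_markers_per_type must be non-negative")
        if self.rna_dispersion <= 0:
            raise ValueError("rna_dispersion must be positive")
        if self.atac_noise_sd < 0:
            raise ValueError("atac_noise_sd must be non-negative")
        if not 0.0 <= self.atac_dropout <= 1.0:
            raise ValueError("atac_dropout must be a probability")
        if self.type_proportions is None:
            props = np.full(self.n_types, 1.0 / self.n_types)
            if self.rare_type_fraction is not None:
                if not 0.0 < self.rare_type_fraction < 1.0:
                    raise ValueError("rare_type_fraction must be in (0, 1)")
                if self.n_types < 2:
                    raise ValueError("rare_type_fraction needs n_types >= 2")
                rest = (1.0 - self.rare_type_fraction) / (self.n_types - 1)
                props = np.array([rest] * (self.n_types - 1) + [self.rare_type_fraction])
            self.type_proportions = props
        self.type_proportions = np.asarray(self.type_proportions, dtype=np.float64)
        if len(self.type_proportions) != self.n_types:
            raise ValueError("type_proportions length must equal n_types")
        if np.any(self.type_proportions < 0) or np.any(self.type_proportions > 1):
            raise ValueError("type_proportions must lie in [0, 1]")
        if abs(self.type_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        if self.n_types > self.n_cells:
            raise ValueError("n_types may not exceed n_cells")
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError("n_markers_per_type * n_types exceeds n_genes")


@dataclass
class SyntheticDataset:
    """Paired RNA counts and ATAC gene-activity values with ground truth."""

    rna: CellFeatureMatrix
    atac: CellFeatureMatrix
    labels: List[str]
    latent: np.ndarray
    marker_map: Dict[str, List[str]]

    def __post_init__(self) -> None:
        if self.rna.cell_ids != self.atac.cell_ids:
            raise ValueError("rna and atac must share identical cell ids in identical order")
        if len(self.labels) != self.rna.n_cells:
            raise ValueError("labels length must equal n_cells")
        feats_r, feats_a = set(self.rna.feature_ids), set(self.atac.feature_ids)
        for t, markers in self.marker_map.items():
            for m in markers:
                if m not in feats_r or m not in feats_a:
                    raise ValueError(f"marker {m!r} missing from a feature list")


def _allocate_type_counts(n_cells: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n_cells over types; every type gets >= 1."""
    raw = props * n_cells
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    # distribute the remainder by descending fractional part (ties: lower index)
    while counts.sum() < n_cells:
        frac = raw - counts
        counts[int(np.argmax(frac))] += 1
    while counts.sum() > n_cells:
        frac = raw - counts
        order = np.argsort(frac)  # most over-allocated first
        for i in order:
            if counts[i] > 1:
                counts[i] -= 1
                break
    return counts


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_paired(config: SimConfig) -> SyntheticDataset:
    """Generate a paired RNA/ATAC dataset from a shared per-cell latent state.

    Deterministic given ``config.seed`` (single ``default_rng`` stream).
    """
    rng = np.random.default_rng(config.seed)
    n, g, t = config.n_cells, config.n_genes, config.n_types

    counts_per_type = _allocate_type_counts(n, config.type_proportions)
    type_of_cell = np.repeat(np.arange(t), counts_per_type)
    type_of_cell = type_of_cell[rng.permutation(n)]
    type_names = [f"type_{i}" for i in range(t)]
    labels = [type_names[i] for i in type_of_cell]

    centroids = rng.normal(size=(t, config.latent_dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    latent = centroids[type_of_cell] + rng.normal(
        scale=LATENT_JITTER_SD, size=(n, config.latent_dim)
    )

    loading = rng.normal(size=(g, config.latent_dim)) / np.sqrt(config.latent_dim)
    gene_ids = [f"gene_{j}" for j in range(g)]

    marker_map: Dict[str, List[str]] = {}
    if config.n_markers_per_type > 0:
        marker_genes = rng.choice(g, size=config.n_markers_per_type * t, replace=False)
        for ti in range(t):
            sel = marker_genes[ti * config.n_markers_per_type : (ti + 1) * config.n_markers_per_type]
            loading[sel] += config.marker_strength * centroids[ti]
            marker_map[type_names[ti]] = [gene_ids[j] for j in sel]

    mu = _softplus(latent @ loading.T)  # (n, g), strictly positive
    mu *= LIBRARY_SIZE / mu.sum(axis=1, keepdims=True)

    # negative binomial via gamma-Poisson mixture; shape r = rna_dispersion
    r = config.rna_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    rna_counts = rng.poisson(lam).astype(np.int64)

    atac_vals = np.log1p(mu)
    if config.atac_noise_sd > 0:
        atac_vals = atac_vals + rng.normal(scale=config.atac_noise_sd, size=atac_vals.shape)
        atac_vals = np.clip(atac_vals, 0.0, None)
    if config.atac_dropout > 0:
        keep = rng.random(atac_vals.shape) >= config.atac_dropout
        atac_vals = atac_vals * keep

    cell_ids = [f"cell_{i}" for i in range(n)]
    rna = CellFeatureMatrix(rna_counts, cell_ids, gene_ids, "RNA")
    atac = CellFeatureMatrix(atac_vals, cell_ids, gene_ids, "ATAC")
    return SyntheticDataset(rna, atac, labels, latent, marker_map)


def write_dataset(ds: SyntheticDataset, dirpath: str) -> dict:
    """Write a dataset as MatrixMarket + TSV sidecars + labels CSV + manifest.

    Returns the manifest (also written as ``manifest.json``).  The marker map
    is embedded in the manifest rather than a separate file.
    """
    os.makedirs(dirpath, exist_ok=True)
    if not os.access(dirpath, os.W_OK):
        raise OSError(f"directory not writable: {dirpath}")

    from scipy.io import mmwrite

    files = {}
    for name, mat in (("rna", ds.rna), ("atac", ds.atac)):
        mtx = f"{name}.mtx"
        mmwrite(os.path.join(dirpath, mtx), sp.csr_matrix(mat.values))
        with open(os.path.join(dirpath, f"{name}.barcodes.tsv"), "w") as fh:
            fh.write("\n".join(mat.cell_ids) + "\n")
        with open(os.path.join(dirpath, f"{name}.features.tsv"), "w") as fh:
            fh.write("\n".join(mat.feature_ids) + "\n")
        files[name] = {
            "matrix": mtx,
            "barcodes": f"{name}.barcodes.tsv",
            "features": f"{name}.features.tsv",
        }

    with open(os.path.join(dirpath, "labels.csv"), "w") as fh:
        fh.write("cell_id,cell_type\n")
        for cid, lab in zip(ds.rna.cell_ids, ds.labels):
            fh.write(f"{cid},{lab}\n")
    files["labels"] = "labels.csv"

    manifest = {"files": files, "n_cells": ds.rna.n_cells, "n_genes": ds.rna.n_features}
    if ds.marker_map:
        manifest["marker_map"] = {k: list(v) for k, v in ds.marker_map.items()}
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
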