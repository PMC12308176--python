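"""Core in-memory containers shared across the pipeline.

A :class:`CellFeatureMatrix` is the universal currency: a cells x features
matrix for one modality, carrying ordered unique cell and feature
identifiers.  Graphs, embeddings and metric reports get their own small
dataclasses so every stage has an explicit, validated interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

Modality = str  # "RNA" | "ATAC"

_VALID_MODALITIES = ("RNA", "ATAC")


def _check_unique(ids: Sequence[str], what: str) -> List[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class CellFeatureMatrix:
    """Cells x features values for one modality.

    ``values`` may be dense ``ndarray`` or any scipy sparse matrix; shape is
    ``(len(cell_ids), len(feature_ids))``.  Identifiers are ordered and
    unique; values must be finite.
    """

    values: "np.ndarray | sp.spmatrix"
    cell_ids: List[str]
    feature_ids: List[str]
    modality: Modality

    def __post_init__(self) -> None:
        if self.modality not in _VALID_MODALITIES:
            raise ValueError(f"modality must be one of {_VALID_MODALITIES}, got {self.modality!r}")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        shape = self.values.shape
        if shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        if np.asarray(data).size and not np.all(np.isfinite(np.asarray(data))):
            raise ValueError("values contain non-finite entries")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def copy_with(self, values=None, feature_ids=None, cell_ids=None) -> "CellFeatureMatrix":
        return CellFeatureMatrix(
            values=self.values if values is None else values,
            cell_ids=list(self.cell_ids) if cell_ids is None else list(cell_ids),
            feature_ids=list(self.feature_ids) if feature_ids is None else list(feature_ids),
            modality=self.modality,
        )


@dataclass
class PeakMatrix:
    """Cells x peaks non-negative counts with genomic intervals (0-based, half-open)."""

    values: "np.ndarray | sp.spmatrix"
    peaks: List[Tuple[str, int, int]]  # (chrom, start, end)
    cell_ids: List[str]

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.cell_ids), len(self.peaks)):
            raise ValueError("values shape inconsistent with cells x peaks")
        for chrom, start, end in self.peaks:
            if not start < end:
                raise ValueError(f"peak {chrom}:{start}-{end} has start >= end")
        data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
        if np.asarray(data).size and np.asarray(data).min() < 0:
            raise ValueError("peak counts must be non-negative")


@dataclass
class GeneAnnotation:
    """Per-gene genomic intervals. Coordinates are 0-based half-open; strand is '+' or '-'."""

    gene_ids: List[str]
    chroms: List[str]
    starts: np.ndarray
    ends: np.ndarray
    strands: List[str]

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        n = len(self.gene_ids)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == len(self.strands) == n):
            raise ValueError("annotation fields have inconsistent lengths")
        if np.any(self.starts >= self.ends):
            raise ValueError("gene start must be < end")
        bad = set(self.strands) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand value(s): {bad}")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class CellGraph:
    """Directed KNN graph over the cells of one modality.

    ``edges`` is an ordered (n_edges, 2) int array of (source, target) pairs
    with no self-edges and no duplicates.
    """

    n_nodes: int
    edges: np.ndarray
    modality: Modality
    k: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-edges are not allowed")
            keys = self.edges[:, 0].astype(np.int64) * self.n_nodes + self.edges[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate directed edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class EmbeddingSet:
    """Per-modality embeddings plus their cell-aligned concatenation.

    ``joint`` stacks all RNA rows then all ATAC rows; ``joint_cell_ids`` and
    ``joint_modality`` tag each joint row.
    """

    Z_R: np.ndarray
    Z_A: np.ndarray
    cell_ids: List[str]

    def __post_init__(self) -> None:
        self.Z_R = np.asarray(self.Z_R, dtype=np.float64)
        self.Z_A = np.asarray(self.Z_A, dtype=np.float64)
        if self.Z_R.shape != self.Z_A.shape:
            raise ValueError("Z_R and Z_A shapes differ")
        if self.Z_R.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match embeddings")
        if not (np.all(np.isfinite(self.Z_R)) and np.all(np.isfinite(self.Z_A))):
            raise ValueError("embeddings contain non-finite values")

    @property
    def n_cells(self) -> int:
        return self.Z_R.shape[0]

    @property
    def joint(self) -> np.ndarray:
        return np.vstack([self.Z_R, self.Z_A])

    @property
    def joint_modality(self) -> np.ndarray:
        n = self.n_cells
        return np.array(["RNA"] * n + ["ATAC"] * n)

    @property
    def joint_cell_ids(self) -> List[str]:
        return list(self.cell_ids) + list(self.cell_ids)

    def split(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.Z_R.copy(), self.Z_A.copy()


@dataclass
class MetricsReport:
    """Integration metric suite: ARI/NMI/F1 (+ their SUM), batch entropy,
    silhouette, per-class transfer accuracy, confusion matrix and optional
    per-feature signal-loss values."""

    ari: float
    nmi: float
    f1: float
    sum_score: float
    batch_entropy: float
    silhouette: float
    per_class_accuracy: Dict[str, float]
    confusion: np.ndarray
    confusion_labels: List[str]
    signal_loss: Dict[str, float] = field(default_factory=dict)
    conventions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.sum_score - (self.ari + self.nmi + self.f1)) > 1e-9:
            raise ValueError("sum_score must equal ari + nmi + f1")
        if not (0.0 <= self.batch_entropy <= 1.0 + 1e-12):
            raise ValueError("batch_entropy out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "ari": float(self.ari),
            "nmi": float(self.nmi),
            "f1": float(self.f1),
            "sum_score": float(self.sum_score),
            "batch_entropy": float(self.batch_entropy),
            "silhouette": float(self.silhouette),
            "per_class_accuracy": {k: float(v) for k, v in self.per_class_accuracy.items()},
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "confusion_labels": list(self.confusion_labels),
            "signal_loss": {k: float(v) for k, v in self.signal_loss.items()},
            "conventions": dict(self.conventions),
        }
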