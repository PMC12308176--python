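"""Label transfer and the integration metric suite.

Metric conventions (recorded in every report): permutation-model ARI; NMI
normalized by the arithmetic mean of the entropies; macro-averaged F1 by
default (weighted available); batch entropy with base-2 logs over k-NN
neighborhoods of the joint embedding; Euclidean silhouette with singleton
clusters contributing 0.  Standard partition metrics are delegated to
scikit-learn; batch entropy, label transfer (with its explicit tie rule) and
silhouette (with the all-singleton convention) are implemented here.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import (adjusted_rand_score, confusion_matrix, f1_score,
                             normalized_mutual_info_score)
from sklearn.neighbors import NearestNeighbors

from .containers import EmbeddingSet, MetricsReport


def join_embeddings(z_r: np.ndarray, z_a: np.ndarray, cell_ids: Sequence[str],
                    cell_ids_a: Optional[Sequence[str]] = None) -> EmbeddingSet:
    """Stack per-modality embeddings into the joint (2N x d) representation.

    If ATAC ids are supplied they must match the RNA ids exactly (same
    order); integration is defined only for paired cells.
    """
    cell_ids = [str(c) for c in cell_ids]
    if cell_ids_a is not None and [str(c) for c in cell_ids_a] != cell_ids:
        raise ValueError("cell id mismatch between modalities")
    return EmbeddingSet(Z_R=np.asarray(z_r), Z_A=np.asarray(z_a), cell_ids=cell_ids)


def transfer_labels(z_r: np.ndarray, labels_r: Sequence[str], z_a: np.ndarray,
                    k_classify: int = 30) -> List[str]:
    """KNN label transfer RNA -> ATAC in embedding space.

    Each ATAC cell takes the majority label of its k nearest RNA cells
    (Euclidean); a majority tie is broken by the label of the single nearest
    neighbor.
    """
    labels_r = [str(l) for l in labels_r]
    if len(labels_r) != z_r.shape[0]:
        raise ValueError("labels_r must cover all RNA cells")
    if k_classify < 1:
        raise ValueError("k_classify must be >= 1")
    if k_classify > z_r.shape[0]:
        raise ValueError(f"k_classify={k_classify} exceeds {z_r.shape[0]} RNA cells")

    nn = NearestNeighbors(n_neighbors=k_classify).fit(np.asarray(z_r, dtype=np.float64))
    _, idx = nn.kneighbors(np.asarray(z_a, dtype=np.float64))
    labels_arr = np.array(labels_r, dtype=object)
    out: List[str] = []
    for row in idx:  # row is sorted by ascending distance
        votes = labels_arr[row]
        uniq, counts = np.unique(votes.astype(str), return_counts=True)
        winners = uniq[counts == counts.max()]
        out.append(str(votes[0]) if len(winners) > 1 else str(winners[0]))
    return out


def ari(labels_true: Sequence, labels_pred: Sequence) -> float:
    """Permutation-model adjusted Rand index."""
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(list(map(str, labels_true)), list(map(str, labels_pred))))


def nmi(labels_true: Sequence, labels_pred: Sequence) -> float:
    """NMI with arithmetic-mean normalization; a zero-entropy partition gives 0."""
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors differ in length")
    lt = list(map(str, labels_true))
    lp = list(map(str, labels_pred))
    if len(set(lt)) == 1 or len(set(lp)) == 1:
        return 0.0  # zero-entropy partition carries no information
    return float(normalized_mutual_info_score(lt, lp, average_method="arithmetic"))


def f1(labels_true: Sequence, labels_pred: Sequence, averaging: str = "macro") -> float:
    """Averaged per-class F1 over the union of observed label universes."""
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors differ in length")
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    lt = list(map(str, labels_true))
    lp = list(map(str, labels_pred))
    labels = sorted(set(lt) | set(lp))
    return float(f1_score(lt, lp, labels=labels, average=averaging, zero_division=0))


def batch_entropy(joint: EmbeddingSet, k_be: int = 15) -> float:
    """Mean base-2 neighborhood entropy of modality membership in [0, 1].

    1 = modalities perfectly mixed; 0 = fully separated.
    """
    z = joint.joint
    n_total = z.shape[0]
    if k_be >= n_total:
        raise ValueError(f"k_be={k_be} must be < {n_total} joint rows")
    is_rna = joint.joint_modality == "RNA"
    nn = NearestNeighbors(n_neighbors=k_be + 1).fit(z)
    _, idx = nn.kneighbors(z)
    ent = np.empty(n_total)
    for r in range(n_total):
        nbrs = idx[r][idx[r] != r][:k_be]
        p = float(np.mean(is_rna[nbrs]))
        if p in (0.0, 1.0):
            ent[r] = 0.0
        else:
            ent[r] = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    return float(ent.mean())


def silhouette(z: np.ndarray, labels: Sequence) -> float:
    """Mean Euclidean silhouette; singleton-label cells contribute 0."""
    labels = np.array(list(map(str, labels)))
    z = np.asarray(z, dtype=np.float64)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 labels")
    d = cdist(z, z)
    n = z.shape[0]
    scores = np.zeros(n)
    sizes = {u: int(np.sum(labels == u)) for u in uniq}
    masks = {u: labels == u for u in uniq}
    for i in range(n):
        li = labels[i]
        if sizes[li] == 1:
            continue  # singleton convention: 0
        a = d[i][masks[li]].sum() / (sizes[li] - 1)  # excludes self (d_ii = 0)
        b = min(d[i][masks[u]].mean() for u in uniq if u != li)
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def signal_loss(original_values: np.ndarray, integrated_values: np.ndarray) -> float:
    """1 - Pearson correlation between two per-cell profiles of one feature."""
    x = np.asarray(original_values, dtype=np.float64).ravel()
    y = np.asarray(integrated_values, dtype=np.float64).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def per_class_accuracy(labels_true: Sequence, labels_pred: Sequence) -> Dict[str, float]:
    lt = np.array(list(map(str, labels_true)))
    lp = np.array(list(map(str, labels_pred)))
    return {str(u): float(np.mean(lp[lt == u] == u)) for u in np.unique(lt)}


def evaluate_integration(embeddings: EmbeddingSet, labels_true_r: Sequence,
                         labels_true_a: Sequence, k_classify: int = 30,
                         k_be: int = 15, averaging: str = "macro") -> MetricsReport:
    """Transfer labels RNA -> ATAC, then compute the full metric suite.

    ARI/NMI/F1 (and SUM = their total) compare transferred vs true ATAC
    labels; batch entropy is computed on the joint embedding; silhouette on
    the joint embedding against the true labels of both modalities.
    """
    pred = transfer_labels(embeddings.Z_R, labels_true_r, embeddings.Z_A, k_classify)
    lt_a = list(map(str, labels_true_a))
    a = ari(lt_a, pred)
    n = nmi(lt_a, pred)
    f = f1(lt_a, pred, averaging)
    be = batch_entropy(embeddings, k_be)
    joint_labels = list(map(str, labels_true_r)) + lt_a
    si = silhouette(embeddings.joint, joint_labels)
    cls = sorted(set(lt_a) | set(pred))
    conf = confusion_matrix(lt_a, pred, labels=cls)
    return MetricsReport(
        ari=a, nmi=n, f1=f, sum_score=a + n + f,
        batch_entropy=be, silhouette=si,
        per_class_accuracy=per_class_accuracy(lt_a, pred),
        confusion=conf, confusion_labels=cls,
        conventions={
            "ari": "permutation-model",
            "nmi": "arithmetic-mean normalization",
            "f1": averaging,
            "batch_entropy": f"k={k_be}, base-2, joint embedding",
            "silhouette": "euclidean, singletons=0, joint embedding + true labels",
            "k_classify": str(k_classify),
        },
    )


def umap_view(joint: EmbeddingSet, n_neighbors: int = 30, seed: int = 0) -> np.ndarray:
    """2-D UMAP layout of the joint embedding (figures only, never metrics)."""
    try:
        import umap
    except ImportError as exc:  # pragma: no cover - present in the target env
        raise ImportError("umap-learn is required for umap_view; metrics are unaffected") from exc
    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(joint.joint))
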