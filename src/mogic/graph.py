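"""Per-modality KNN graph construction.

Each cell is connected by a directed edge to its k nearest neighbours under
Euclidean distance in PCA space.  A fraction of *unidirectional* edges (those
whose reverse edge is absent) is then removed at random: in small clusters a
fixed k inevitably reaches across cell-type boundaries, and such spurious
links are typically one-way, so pruning them sparsifies exactly the risky
part of the graph while mutual (reciprocal) edges are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import CellFeatureMatrix, CellGraph


@dataclass
class GraphConfig:
    k: int = 20
    edge_drop_rate: float = 0.2
    seed: int = 0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not 0.0 <= self.edge_drop_rate < 1.0:
            raise ValueError("edge_drop_rate must be in [0, 1)")
        if self.metric != "euclidean":
            raise ValueError("only the Euclidean metric is supported")


def pairwise_distances(x: CellFeatureMatrix) -> np.ndarray:
    """Full symmetric Euclidean distance matrix with zero diagonal."""
    v = x.dense().astype(np.float64)
    d = cdist(v, v, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    return d


def _row_topk(dist_row: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k nearest other nodes for node i; ties -> smaller index."""
    d = dist_row.copy()
    d[i] = np.inf  # exclude self
    order = np.lexsort((np.arange(len(d)), d))  # by (distance, index)
    return order[:k]


def knn_edges(d: np.ndarray, cfg: GraphConfig, modality: str = "RNA") -> CellGraph:
    """Directed KNN edge list from a distance matrix.

    Every node gets exactly k outgoing edges to its k nearest other nodes;
    ties broken by smaller target index; edges sorted by
    (source, distance, target).
    """
    n = d.shape[0]
    if cfg.k >= n:
        raise ValueError(f"k={cfg.k} must be < n_nodes={n}")
    edges = np.empty((n * cfg.k, 2), dtype=np.int64)
    for i in range(n):
        nbrs = _row_topk(d[i], i, cfg.k)
        edges[i * cfg.k : (i + 1) * cfg.k, 0] = i
        edges[i * cfg.k : (i + 1) * cfg.k, 1] = nbrs
    return CellGraph(n_nodes=n, edges=edges, modality=modality, k=cfg.k)


def drop_unidirectional(g: CellGraph, cfg: GraphConfig) -> CellGraph:
    """Randomly remove unidirectional edges with probability edge_drop_rate.

    Mutual edges (reverse edge present) are always kept.  Deterministic
    given cfg.seed; edge order of the survivors is preserved.
    """
    if cfg.edge_drop_rate == 0 or g.n_edges == 0:
        return CellGraph(g.n_nodes, g.edges.copy(), g.modality, g.k)
    keys = set(map(tuple, g.edges.tolist()))
    is_mutual = np.array([(j, i) in keys for i, j in g.edges], dtype=bool)
    rng = np.random.default_rng(cfg.seed)
    u = rng.random(g.n_edges)
    keep = is_mutual | (u >= cfg.edge_drop_rate)
    return CellGraph(g.n_nodes, g.edges[keep], g.modality, g.k)


def build_modality_graph(x: CellFeatureMatrix, cfg: GraphConfig, chunk_size: int = 2048) -> CellGraph:
    """pairwise_distances -> knn_edges -> drop_unidirectional.

    For large inputs the distance matrix is never materialized: rows are
    processed in chunks of ``chunk_size`` cells with the same exact top-k and
    tie rule, keeping memory O(n * chunk_size).
    """
    v = x.dense().astype(np.float64)
    n = v.shape[0]
    if cfg.k >= n:
        raise ValueError(f"k={cfg.k} must be < n_nodes={n}")
    if n <= chunk_size:
        g = knn_edges(pairwise_distances(x), cfg, x.modality)
    else:
        edges = np.empty((n * cfg.k, 2), dtype=np.int64)
        for lo in range(0, n, chunk_size):
            hi = min(lo + chunk_size, n)
            block = cdist(v[lo:hi], v, metric="euclidean")
            for r in range(hi - lo):
                i = lo + r
                nbrs = _row_topk(block[r], i, cfg.k)
                edges[i * cfg.k : (i + 1) * cfg.k, 0] = i
                edges[i * cfg.k : (i + 1) * cfg.k, 1] = nbrs
        g = CellGraph(n_nodes=n, edges=edges, modality=x.modality, k=cfg.k)
    return drop_unidirectional(g, cfg)


def write_edge_list(g: CellGraph, path: str) -> None:
    """TSV export ``src\\tdst`` (0-based), one directed edge per line."""
    with open(path, "w") as fh:
        fh.write("src\tdst\n")
        for i, j in g.edges:
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: str, n_nodes: int, modality: str = "RNA", k: int = 0) -> CellGraph:
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "src\tdst":
            raise ValueError(f"{path}: expected header 'src\\tdst'")
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: malformed edge line")
            edges.append((int(parts[0]), int(parts[1])))
    return CellGraph(n_nodes=n_nodes, edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
                     modality=modality, k=k)
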