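"""Full-graph contrastive training of the shared encoder.

Every epoch embeds all cells of both modalities (full batch, so the
contrastive denominator ranges over every cell, as the objective requires),
computes the loss and takes one Adam step over all five weight matrices.
Training is single-threaded-deterministic given the seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .containers import CellGraph
from .nn import (EncoderModel, ModelConfig, encode, init_model, loss_and_grads,
                 normalize_adjacency)


@dataclass
class TrainConfig:
    lr: float = 0.0006
    epochs: int = 500
    tau: float = 0.1
    loss_kind: str = "contrastive"  # "contrastive" | "mse"
    log_every: int = 50
    seed: int = 0
    early_stop_patience: Optional[int] = None
    early_stop_rel_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.loss_kind not in ("contrastive", "mse"):
            raise ValueError("loss_kind must be 'contrastive' or 'mse'")


@dataclass
class TrainTrace:
    losses: List[float] = field(default_factory=list)
    pair_cosine: List[float] = field(default_factory=list)  # mean within-pair cos per epoch
    pair_margin: List[float] = field(default_factory=list)  # diag - mean off-diag cosine
    seconds: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.losses)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8), no weight decay."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, w in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            w -= update.astype(w.dtype)


def _pair_alignment(z_r: np.ndarray, z_a: np.ndarray) -> Tuple[float, float]:
    """(mean within-pair cosine, alignment margin = diag - mean off-diag cosine)."""
    u = z_r / np.maximum(np.linalg.norm(z_r, axis=1, keepdims=True), 1e-30)
    v = z_a / np.maximum(np.linalg.norm(z_a, axis=1, keepdims=True), 1e-30)
    s = u @ v.T
    n = s.shape[0]
    diag = float(np.trace(s) / n)
    off = float((s.sum() - np.trace(s)) / max(n * n - n, 1))
    return diag, diag - off


def train(model: EncoderModel, g_r: CellGraph, g_a: CellGraph,
          x_r: np.ndarray, x_a: np.ndarray, cfg: TrainConfig,
          verbose: bool = False) -> Tuple[EncoderModel, TrainTrace]:
    """Train the shared encoder on both modality graphs.

    Inputs must be paired: same number of cells in the same order, and equal
    feature dimension (one encoder serves both views).  Raises on NaN loss
    (with the epoch index) rather than continuing silently.
    """
    if x_r.shape[0] != x_a.shape[0]:
        raise ValueError(f"unpaired inputs: {x_r.shape[0]} RNA vs {x_a.shape[0]} ATAC cells")
    if x_r.shape[1] != x_a.shape[1]:
        raise ValueError("shared encoder requires equal feature dimensions")
    if g_r.n_nodes != x_r.shape[0] or g_a.n_nodes != x_a.shape[0]:
        raise ValueError("graph node count does not match cell count")

    model = model.copy()
    use_graph = model.config.encoder_kind == "GCN"
    a_r = normalize_adjacency(g_r, model.config.self_loops) if use_graph else None
    a_a = normalize_adjacency(g_a, model.config.self_loops) if use_graph else None
    x_r32 = np.ascontiguousarray(x_r, dtype=np.float32)
    x_a32 = np.ascontiguousarray(x_a, dtype=np.float32)

    opt = Adam(model.params(), cfg.lr)
    trace = TrainTrace()
    best, since_best = np.inf, 0
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        loss, grads = loss_and_grads(model, a_r, x_r32, a_a, x_a32,
                                     cfg.tau, cfg.loss_kind)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        opt.step(model.params(), grads)

        z_r = encode(model, a_r, x_r32)
        z_a = encode(model, a_a, x_a32)
        trace.losses.append(loss)
        diag, margin = _pair_alignment(z_r, z_a)
        trace.pair_cosine.append(diag)
        trace.pair_margin.append(margin)
        trace.seconds.append(time.perf_counter() - t0)
        if verbose and cfg.log_every and epoch % cfg.log_every == 0:
            print(f"epoch {epoch:4d}  loss {loss:.5f}  pair-cos {trace.pair_cosine[-1]:.4f}")

        if cfg.early_stop_patience is not None:
            if loss < best * (1.0 - cfg.early_stop_rel_tol):
                best, since_best = loss, 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
    return model, trace


def embed(model: EncoderModel, g: Optional[CellGraph], x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass to the projector output (no dropout anywhere)."""
    a_hat = None
    if model.config.encoder_kind == "GCN":
        if g is None:
            raise ValueError("GCN encoder requires a graph")
        a_hat = normalize_adjacency(g, model.config.self_loops)
    return encode(model, a_hat, np.ascontiguousarray(x, dtype=np.float32))
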