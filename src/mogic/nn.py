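"""Encoder, projector and contrastive objectives, in plain NumPy/SciPy.

Architecture
------------
A three-layer graph convolutional encoder over the symmetrically normalized
adjacency ``Â = D^(-1/2) A D^(-1/2)``:

    H1 = ReLU(Â X W0)
    H2 = ReLU(Â H1 W1)
    H3 = Â H2 W2            (no activation; the projector supplies one)

followed by a two-layer projection head

    Z = ReLU(H3 Wp1) Wp2.

All layers are bias-free.  The same weights encode both modalities (a shared
encoder), and an MLP ablation replaces Â with the identity.

Objectives
----------
The cross-modality contrastive (InfoNCE) loss treats cell *i*'s RNA and ATAC
embeddings as a positive pair and every other ATAC cell as a negative:

    L = -(1/N) sum_i log[ exp(sim(z_i^R, z_i^A)/tau)
                          / sum_j exp(sim(z_i^R, z_j^A)/tau) ]

with cosine similarity and temperature ``tau``.  The MSE ablation replaces
the cross-entropy with a squared deviation of the same softmax diagonal from
one.  Gradients for both losses and the full encoder/projector stack are
implemented by hand (verified against finite differences in the test suite).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .containers import CellGraph


@dataclass
class ModelConfig:
    in_dim: int = 30
    hidden_dim: int = 300
    out_dim: int = 128
    encoder_kind: str = "GCN"  # "GCN" | "MLP"
    self_loops: bool = True
    tau: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("in_dim", "hidden_dim", "out_dim"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        kind = self.encoder_kind.upper()
        if kind not in ("GCN", "MLP"):
            raise ValueError("encoder_kind must be 'GCN' or 'MLP'")
        self.encoder_kind = kind


@dataclass
class EncoderModel:
    """Weight matrices of the shared encoder + projector.

    Shape chain: in_dim -> hidden -> hidden -> hidden (encoder)
                 -> hidden -> out_dim (projector).
    """

    W0: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    Wp1: np.ndarray
    Wp2: np.ndarray
    config: ModelConfig

    PARAM_NAMES = ("W0", "W1", "W2", "Wp1", "Wp2")

    def __post_init__(self) -> None:
        c = self.config
        expected = {
            "W0": (c.in_dim, c.hidden_dim),
            "W1": (c.hidden_dim, c.hidden_dim),
            "W2": (c.hidden_dim, c.hidden_dim),
            "Wp1": (c.hidden_dim, c.hidden_dim),
            "Wp2": (c.hidden_dim, c.out_dim),
        }
        for name, shape in expected.items():
            w = getattr(self, name)
            if w.shape != shape:
                raise ValueError(f"{name} has shape {w.shape}, expected {shape}")

    def params(self) -> Dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.PARAM_NAMES}

    def n_parameters(self) -> int:
        return sum(w.size for w in self.params().values())

    def copy(self) -> "EncoderModel":
        return EncoderModel(*(getattr(self, n).copy() for n in self.PARAM_NAMES), config=self.config)


def init_model(cfg: ModelConfig) -> EncoderModel:
    """Glorot-uniform initialization, deterministic given cfg.seed.

    Each W ~ U(-a, a) with a = sqrt(6 / (fan_in + fan_out)).
    """
    rng = np.random.default_rng(cfg.seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        a = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-a, a, size=(fan_in, fan_out)).astype(np.float32)

    h = cfg.hidden_dim
    return EncoderModel(
        W0=glorot(cfg.in_dim, h),
        W1=glorot(h, h),
        W2=glorot(h, h),
        Wp1=glorot(h, h),
        Wp2=glorot(h, cfg.out_dim),
        config=cfg,
    )


def normalize_adjacency(g: CellGraph, self_loops: bool = True) -> sp.csr_matrix:
    """Symmetrically normalized adjacency Â = D^(-1/2) A D^(-1/2).

    A is the 0/1 symmetrization (union) of the directed edge set, plus the
    identity when ``self_loops``.  Isolated nodes (degree 0) get zero rows
    with a warning.
    """
    n = g.n_nodes
    if g.n_edges:
        i, j = g.edges[:, 0], g.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        a.data[:] = 1.0  # union, not sum
    else:
        a = sp.csr_matrix((n, n))
    if self_loops:
        a = a + sp.identity(n, format="csr")
        a.data[:] = 1.0
    deg = np.asarray(a.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated node(s); their rows of Â are zero")
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[isolated] = 0.0
    d_half = sp.diags(dinv)
    return (d_half @ a @ d_half).tocsr()


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_forward(model: EncoderModel, a_hat: sp.spmatrix, x: np.ndarray) -> np.ndarray:
    """Three graph-convolution layers; no activation on the last."""
    h1 = _relu(a_hat @ (x @ model.W0))
    h2 = _relu(a_hat @ (h1 @ model.W1))
    return a_hat @ (h2 @ model.W2)


def mlp_forward(model: EncoderModel, x: np.ndarray) -> np.ndarray:
    """The GCN stack with Â = I (the non-graph ablation)."""
    h1 = _relu(x @ model.W0)
    h2 = _relu(h1 @ model.W1)
    return h2 @ model.W2


def project(model: EncoderModel, h3: np.ndarray) -> np.ndarray:
    """Two-layer projection head: Z = ReLU(H3 Wp1) Wp2."""
    return _relu(h3 @ model.Wp1) @ model.Wp2


def encode(model: EncoderModel, a_hat: Optional[sp.spmatrix], x: np.ndarray) -> np.ndarray:
    """Full forward pass (encoder + projector) honoring encoder_kind."""
    if model.config.encoder_kind == "MLP" or a_hat is None:
        h3 = mlp_forward(model, x)
    else:
        h3 = gcn_forward(model, a_hat, x)
    return project(model, h3)


# ---------------------------------------------------------------------------
# similarity + losses
# ---------------------------------------------------------------------------

_ZERO_NORM_TOL = 1e-12


def _row_normalize(z: np.ndarray, name: str) -> Tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1)
    bad = np.flatnonzero(norms <= _ZERO_NORM_TOL)
    if bad.size:
        raise ValueError(f"cosine similarity undefined: all-zero embedding row for cell "
                         f"{bad[0]} in {name}")
    return z / norms[:, None], norms


def cosine_similarity_matrix(z_r: np.ndarray, z_a: np.ndarray) -> np.ndarray:
    """S with S[i, j] = cos(z_i^R, z_j^A); errors on an all-zero row."""
    u, _ = _row_normalize(np.asarray(z_r, dtype=np.float64), "Z_R")
    v, _ = _row_normalize(np.asarray(z_a, dtype=np.float64), "Z_A")
    return u @ v.T


def contrastive_loss(z_r: np.ndarray, z_a: np.ndarray, tau: float,
                     symmetric: bool = False) -> float:
    """RNA-anchored InfoNCE loss over all N cells (log-sum-exp stabilized).

    With ``symmetric=True`` the ATAC-anchored term is averaged in.
    """
    if z_r.shape != z_a.shape:
        raise ValueError("Z_R and Z_A must have equal shapes")
    s = cosine_similarity_matrix(z_r, z_a) / tau
    from scipy.special import logsumexp

    loss = float(np.mean(logsumexp(s, axis=1) - np.diag(s)))
    if symmetric:
        loss = 0.5 * (loss + float(np.mean(logsumexp(s, axis=0) - np.diag(s))))
    return loss


def _softmax_rows(s: np.ndarray) -> np.ndarray:
    m = s.max(axis=1, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(axis=1, keepdims=True)


def mse_ablation_loss(z_r: np.ndarray, z_a: np.ndarray, tau: float) -> float:
    """Mean squared deviation of the softmax diagonal from 1 (loss ablation)."""
    if z_r.shape != z_a.shape:
        raise ValueError("Z_R and Z_A must have equal shapes")
    p = _softmax_rows(cosine_similarity_matrix(z_r, z_a) / tau)
    return float(np.mean((np.diag(p) - 1.0) ** 2))


# ---------------------------------------------------------------------------
# gradients (used by the trainer; finite-difference-checked in tests)
# ---------------------------------------------------------------------------

def _loss_grad_wrt_embeddings(z_r: np.ndarray, z_a: np.ndarray, tau: float,
                              loss_kind: str) -> Tuple[float, np.ndarray, np.ndarray]:
    """Loss value and dL/dZ_R, dL/dZ_A for either objective."""
    z_r64 = np.asarray(z_r, dtype=np.float64)
    z_a64 = np.asarray(z_a, dtype=np.float64)
    u, nu = _row_normalize(z_r64, "Z_R")
    v, nv = _row_normalize(z_a64, "Z_A")
    s = (u @ v.T) / tau
    n = s.shape[0]
    p = _softmax_rows(s)
    if loss_kind == "contrastive":
        from scipy.special import logsumexp

        loss = float(np.mean(logsumexp(s, axis=1) - np.diag(s)))
        g_s = (p - np.eye(n)) / (n * tau)  # dL/dS_cos, chain through /tau
    elif loss_kind == "mse":
        diag = np.diag(p)
        loss = float(np.mean((diag - 1.0) ** 2))
        # dL/dp_ii = 2(p_ii - 1)/n ; dp_ii/dS_ij = p_ii (delta_ij - p_ij)/tau
        coeff = 2.0 * (diag - 1.0) / n * diag  # per-row factor
        g_s = coeff[:, None] * (np.eye(n) - p) / tau
    else:
        raise ValueError(f"unknown loss_kind {loss_kind!r}")

    # S_cos = U V^T; back through row normalization u = z/|z|
    g_u = g_s @ v
    g_v = g_s.T @ u
    g_zr = (g_u - (np.sum(g_u * u, axis=1, keepdims=True)) * u) / nu[:, None]
    g_za = (g_v - (np.sum(g_v * v, axis=1, keepdims=True)) * v) / nv[:, None]
    return loss, g_zr, g_za


def _forward_cached(model: EncoderModel, a_hat: Optional[sp.spmatrix],
                    x: np.ndarray) -> Tuple[np.ndarray, dict]:
    """Forward pass keeping the intermediates needed for backprop."""
    use_graph = model.config.encoder_kind == "GCN" and a_hat is not None

    def prop(m: np.ndarray) -> np.ndarray:
        return a_hat @ m if use_graph else m

    a1 = prop(x)
    b1 = a1 @ model.W0
    h1 = _relu(b1)
    a2 = prop(h1)
    b2 = a2 @ model.W1
    h2 = _relu(b2)
    a3 = prop(h2)
    h3 = a3 @ model.W2
    pre = h3 @ model.Wp1
    h = _relu(pre)
    z = h @ model.Wp2
    cache = dict(a1=a1, b1=b1, a2=a2, b2=b2, a3=a3, h3=h3, pre=pre, h=h,
                 use_graph=use_graph, a_hat=a_hat)
    return z, cache


def _backward(model: EncoderModel, cache: dict, g_z: np.ndarray,
              grads: Dict[str, np.ndarray]) -> None:
    """Accumulate dL/dW into ``grads`` given dL/dZ (Â symmetric: Â^T = Â)."""
    a_hat, use_graph = cache["a_hat"], cache["use_graph"]

    def backprop_prop(g: np.ndarray) -> np.ndarray:
        return a_hat @ g if use_graph else g

    grads["Wp2"] += cache["h"].T @ g_z
    g_h = g_z @ model.Wp2.T
    g_pre = g_h * (cache["pre"] > 0)
    grads["Wp1"] += cache["h3"].T @ g_pre
    g_h3 = g_pre @ model.Wp1.T

    grads["W2"] += cache["a3"].T @ g_h3
    g_h2 = backprop_prop(g_h3 @ model.W2.T)
    g_b2 = g_h2 * (cache["b2"] > 0)
    grads["W1"] += cache["a2"].T @ g_b2
    g_h1 = backprop_prop(g_b2 @ model.W1.T)
    g_b1 = g_h1 * (cache["b1"] > 0)
    grads["W0"] += cache["a1"].T @ g_b1


def loss_and_grads(model: EncoderModel, a_r: Optional[sp.spmatrix], x_r: np.ndarray,
                   a_a: Optional[sp.spmatrix], x_a: np.ndarray, tau: float,
                   loss_kind: str = "contrastive") -> Tuple[float, Dict[str, np.ndarray]]:
    """One full-batch forward + backward over both modality views.

    The encoder is shared, so weight gradients from the RNA and ATAC paths
    accumulate into the same matrices.
    """
    z_r, cache_r = _forward_cached(model, a_r, x_r)
    z_a, cache_a = _forward_cached(model, a_a, x_a)
    loss, g_zr, g_za = _loss_grad_wrt_embeddings(z_r, z_a, tau, loss_kind)
    grads = {n: np.zeros_like(getattr(model, n), dtype=np.float64) for n in model.PARAM_NAMES}
    _backward(model, cache_r, g_zr, grads)
    _backward(model, cache_a, g_za, grads)
    return loss, grads


# ---------------------------------------------------------------------------
# checkpoint io
# ---------------------------------------------------------------------------

def save_checkpoint(model: EncoderModel, path: str) -> None:
    """NPZ archive with the five weight matrices and the config as JSON."""
    cfg = model.config
    cfg_json = json.dumps({
        "in_dim": cfg.in_dim, "hidden_dim": cfg.hidden_dim, "out_dim": cfg.out_dim,
        "encoder_kind": cfg.encoder_kind, "self_loops": cfg.self_loops,
        "tau": cfg.tau, "seed": cfg.seed,
    })
    np.savez(path, config_json=np.array(cfg_json), **model.params())


def load_checkpoint(path: str) -> EncoderModel:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["config_json"])))
        weights = {n: data[n] for n in EncoderModel.PARAM_NAMES}
    return EncoderModel(**weights, config=cfg)
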