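"""Encoder/projector/loss oracle tests, including finite-difference gradient checks."""

import numpy as np
import pytest
import scipy.sparse as sp

from mogic import (CellGraph, ModelConfig, contrastive_loss, gcn_forward,
                   init_model, load_checkpoint, mlp_forward, mse_ablation_loss,
                   normalize_adjacency, project, save_checkpoint)
from mogic.nn import EncoderModel, cosine_similarity_matrix, loss_and_grads


def random_graph(rng, n, p=0.2):
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = np.argwhere(mask)
    if len(edges) == 0:
        edges = np.array([(0, 1)])
    return CellGraph(n, edges, "RNA", k=0)


def square_model(dim, seed=0):
    """All-square model so identity-weight constructions are possible."""
    cfg = ModelConfig(in_dim=dim, hidden_dim=dim, out_dim=dim, seed=seed)
    return init_model(cfg)


class TestNormalizeAdjacency:
    def test_single_edge_no_self_loops(self):
        g = CellGraph(2, np.array([(0, 1)]), "RNA", 1)
        a = normalize_adjacency(g, self_loops=False).todense()
        assert np.allclose(a, [[0, 1], [1, 0]])

    def test_single_edge_with_self_loops(self):
        g = CellGraph(2, np.array([(0, 1)]), "RNA", 1)
        a = normalize_adjacency(g, self_loops=True).todense()
        assert np.allclose(a, [[0.5, 0.5], [0.5, 0.5]])

    def test_directed_edges_symmetrized_by_union(self):
        g = CellGraph(3, np.array([(0, 1), (1, 0), (2, 0)]), "RNA", 1)
        a = normalize_adjacency(g, self_loops=False).todense()
        assert np.allclose(a, a.T)
        assert a[0, 2] > 0 and a[2, 0] > 0

    @pytest.mark.parametrize("self_loops", [True, False])
    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_spectral_radius(self, seed, self_loops):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(5, 40)))
        a = normalize_adjacency(g, self_loops=self_loops).todense()
        assert np.max(np.abs(a - a.T)) < 1e-9
        assert np.min(a) >= 0
        evals = np.linalg.eigvalsh(a)
        assert np.max(np.abs(evals)) <= 1 + 1e-6

    def test_disjoint_cliques_block_diagonal(self):
        edges = ([(i, j) for i in range(4) for j in range(4) if i != j]
                 + [(4 + i, 4 + j) for i in range(3) for j in range(3) if i != j])
        g = CellGraph(7, np.array(edges), "RNA", 1)
        a = normalize_adjacency(g, self_loops=True).todense()
        assert not a[:4, 4:].any() and not a[4:, :4].any()

    def test_isolated_node_zero_row_with_warning(self):
        g = CellGraph(3, np.array([(0, 1)]), "RNA", 1)
        with pytest.warns(UserWarning, match="isolated"):
            a = normalize_adjacency(g, self_loops=False).todense()
        assert not a[2].any()


class TestForwardPasses:
    def test_identity_propagation(self):
        # edgeless graph + self-loops -> A_hat = I; identity weights pass X through
        model = square_model(4)
        for name in model.PARAM_NAMES:
            setattr(model, name, np.eye(4, dtype=np.float32))
        a = normalize_adjacency(CellGraph(5, np.empty((0, 2)), "RNA", 0), self_loops=True)
        x = np.abs(np.random.default_rng(0).normal(size=(5, 4))).astype(np.float32)
        assert np.allclose(gcn_forward(model, a, x), x, atol=1e-6)
        assert np.allclose(project(model, x), x, atol=1e-6)

    def test_zero_first_layer_kills_output(self):
        model = square_model(4)
        model.W0 = np.zeros_like(model.W0)
        a = sp.identity(5, format="csr")
        x = np.random.default_rng(1).normal(size=(5, 4))
        assert not gcn_forward(model, a, x).any()

    @pytest.mark.parametrize("self_loops", [True, False])
    @pytest.mark.parametrize("seed", range(12))
    def test_sparse_equals_dense_oracle(self, seed, self_loops):
        """Sparse propagation equals the dense A_hat triple-product oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        g = random_graph(rng, n)
        model = init_model(ModelConfig(in_dim=6, hidden_dim=9, out_dim=5, seed=seed))
        a = normalize_adjacency(g, self_loops=self_loops)
        x = rng.normal(size=(n, 6)).astype(np.float32)
        ad = np.asarray(a.todense(), dtype=np.float64)
        h1 = np.maximum(ad @ (x @ model.W0.astype(np.float64)), 0)
        h2 = np.maximum(ad @ (h1 @ model.W1.astype(np.float64)), 0)
        ref = ad @ (h2 @ model.W2.astype(np.float64))
        assert np.allclose(gcn_forward(model, a, x), ref, atol=1e-5)

    def test_mlp_equals_gcn_on_edgeless_graph(self):
        rng = np.random.default_rng(3)
        model = init_model(ModelConfig(in_dim=5, hidden_dim=7, out_dim=4, seed=3))
        a = normalize_adjacency(CellGraph(8, np.empty((0, 2)), "RNA", 0), self_loops=True)
        x = rng.normal(size=(8, 5)).astype(np.float32)
        assert np.allclose(mlp_forward(model, x), gcn_forward(model, a, x), atol=1e-6)

    def test_mlp_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(4)
        model = init_model(ModelConfig(in_dim=3, hidden_dim=4, out_dim=2, seed=4))
        x = rng.normal(size=(5, 3))
        out = mlp_forward(model, x)
        W0, W1, W2 = (m.astype(np.float64) for m in (model.W0, model.W1, model.W2))
        for i in range(5):
            h1 = [max(sum(x[i, a] * W0[a, b] for a in range(3)), 0) for b in range(4)]
            h2 = [max(sum(h1[a] * W1[a, b] for a in range(4)), 0) for b in range(4)]
            h3 = [sum(h2[a] * W2[a, b] for a in range(4)) for b in range(4)]
            assert np.allclose(out[i], h3, atol=1e-6)

    def test_projector_cases(self):
        model = square_model(3)
        h3 = np.abs(np.random.default_rng(5).normal(size=(4, 3)))
        model.Wp1 = model.Wp2 = np.eye(3, dtype=np.float32)
        assert np.allclose(project(model, h3), h3, atol=1e-6)
        model.Wp2 = np.zeros_like(model.Wp2)
        assert not project(model, h3).any()


class TestContrastiveLoss:
    def test_single_cell_zero_loss(self):
        z = np.array([[1.0, 2.0]])
        assert contrastive_loss(z, z, tau=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_pair_closed_form(self):
        """N=2, Z_R = Z_A = I, tau=1: each row's loss is ln(1 + e^-1)."""
        z = np.eye(2)
        expected = np.log(1.0 + np.exp(-1.0))
        assert contrastive_loss(z, z, tau=1.0) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(2, 16)), int(rng.integers(2, 8))
        tau = float(rng.uniform(0.05, 1.5))
        zr, za = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        total = 0.0
        for i in range(n):
            def cos(u, v):
                return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            num = np.exp(cos(zr[i], za[i]) / tau)
            den = sum(np.exp(cos(zr[i], za[j]) / tau) for j in range(n))
            total += -np.log(num / den)
        assert contrastive_loss(zr, za, tau) == pytest.approx(total / n, abs=1e-6)
        assert contrastive_loss(zr, za, tau) <= np.log(n) + 1.0 / tau

    def test_zero_row_rejected_naming_cell(self):
        zr = np.array([[1.0, 0.0], [0.0, 0.0]])
        za = np.eye(2)
        with pytest.raises(ValueError, match="cell 1"):
            contrastive_loss(zr, za, tau=0.1)

    def test_orthogonal_rotation_invariance(self):
        rng = np.random.default_rng(11)
        zr, za = rng.normal(size=(12, 6)), rng.normal(size=(12, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert contrastive_loss(zr @ q, za @ q, 0.3) == pytest.approx(
            contrastive_loss(zr, za, 0.3), abs=1e-9)

    def test_row_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        zr, za = rng.normal(size=(10, 5)), rng.normal(size=(10, 5))
        s1 = rng.uniform(0.1, 9.0, size=(10, 1))
        s2 = rng.uniform(0.1, 9.0, size=(10, 1))
        assert contrastive_loss(zr * s1, za * s2, 0.2) == pytest.approx(
            contrastive_loss(zr, za, 0.2), abs=1e-9)

    def test_smaller_tau_sharpens_diagonally_dominant_loss(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(8, 6))
        zr = base + 0.05 * rng.normal(size=(8, 6))
        za = base  # diagonal similarity dominates by construction
        losses = [contrastive_loss(zr, za, t) for t in (1.0, 0.5, 0.2, 0.1)]
        assert np.all(np.diff(losses) < 0)

    def test_symmetric_option_averages_both_anchors(self):
        rng = np.random.default_rng(14)
        zr, za = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        sym = contrastive_loss(zr, za, 0.3, symmetric=True)
        assert sym == pytest.approx(
            0.5 * (contrastive_loss(zr, za, 0.3) + contrastive_loss(za, zr, 0.3)), abs=1e-9)


class TestMseAblationLoss:
    def test_single_cell_zero(self):
        z = np.array([[3.0, 1.0]])
        assert mse_ablation_loss(z, z, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_similarities_closed_form(self):
        # all RNA rows identical and all ATAC rows identical -> all sims equal
        n = 5
        zr = np.tile([1.0, 1.0], (n, 1))
        za = np.tile([1.0, 0.0], (n, 1))
        expected = (1.0 - 1.0 / n) ** 2
        assert mse_ablation_loss(zr, za, 0.7) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        n, d = int(rng.integers(2, 12)), int(rng.integers(2, 6))
        tau = float(rng.uniform(0.1, 1.0))
        zr, za = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        s = cosine_similarity_matrix(zr, za) / tau
        total = 0.0
        for i in range(n):
            p_ii = np.exp(s[i, i]) / sum(np.exp(s[i, j]) for j in range(n))
            total += (p_ii - 1.0) ** 2
        assert mse_ablation_loss(zr, za, tau) == pytest.approx(total / n, abs=1e-6)


class TestGradients:
    @pytest.mark.parametrize("loss_kind", ["contrastive", "mse"])
    def test_finite_difference_check(self, loss_kind):
        """Analytic weight gradients match central finite differences."""
        rng = np.random.default_rng(0)
        model = init_model(ModelConfig(in_dim=3, hidden_dim=4, out_dim=3, tau=0.4, seed=2))
        for n in model.PARAM_NAMES:
            setattr(model, n, getattr(model, n).astype(np.float64))
        n_cells = 6
        edges = np.array([(i, (i + 1) % n_cells) for i in range(n_cells)])
        g = CellGraph(n_cells, edges, "RNA", 1)
        a = normalize_adjacency(g)
        xr, xa = rng.normal(size=(n_cells, 3)), rng.normal(size=(n_cells, 3))
        _, grads = loss_and_grads(model, a, xr, a, xa, 0.4, loss_kind)
        eps = 1e-6
        for name in model.PARAM_NAMES:
            W = getattr(model, name)
            for idx in [(0, 0), (1, 2), (W.shape[0] - 1, W.shape[1] - 1)]:
                old = W[idx]
                W[idx] = old + eps
                lp, _ = loss_and_grads(model, a, xr, a, xa, 0.4, loss_kind)
                W[idx] = old - eps
                lm, _ = loss_and_grads(model, a, xr, a, xa, 0.4, loss_kind)
                W[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(fd, abs=1e-6, rel=1e-4)


class TestInitAndCheckpoint:
    def test_seed_determinism(self):
        cfg = ModelConfig(seed=5)
        m1, m2 = init_model(cfg), init_model(cfg)
        for n in m1.PARAM_NAMES:
            assert np.array_equal(getattr(m1, n), getattr(m2, n))
        m3 = init_model(ModelConfig(seed=6))
        assert not np.array_equal(m1.W0, m3.W0)

    def test_glorot_scale(self):
        """Sample sd of a 300x300 layer within 20% of sqrt(2/(fan_in+fan_out))."""
        model = init_model(ModelConfig(in_dim=30, hidden_dim=300, out_dim=128, seed=0))
        nominal = np.sqrt(2.0 / 600.0)  # uniform(-a,a) has sd a/sqrt(3), a=sqrt(6/600)
        assert abs(model.W1.std() - nominal) / nominal < 0.2

    def test_checkpoint_round_trip(self, tmp_path):
        model = init_model(ModelConfig(in_dim=7, hidden_dim=9, out_dim=5,
                                       encoder_kind="MLP", tau=0.25, seed=8))
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == model.config
        for n in model.PARAM_NAMES:
            assert np.array_equal(getattr(loaded, n), getattr(model, n))

    def test_shape_chain_validated(self):
        cfg = ModelConfig(in_dim=4, hidden_dim=5, out_dim=3)
        good = init_model(cfg)
        with pytest.raises(ValueError, match="W1"):
            EncoderModel(W0=good.W0, W1=np.zeros((2, 2), dtype=np.float32),
                         W2=good.W2, Wp1=good.Wp1, Wp2=good.Wp2, config=cfg)
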