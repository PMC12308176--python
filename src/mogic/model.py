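"""High-level modelling interface.

:class:`GraphContrastiveIntegration` is constructed from paired raw matrices
(statsmodels-style: the data goes into the model object, ``fit()`` returns a
results object).  Fitting runs preprocessing, per-modality KNN graph
construction and full-graph contrastive training; the returned
:class:`IntegrationResults` carries the trained weights, embeddings, training
trace, transferred labels and the metric suite, with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import EvalConfig, PipelineConfig
from .containers import CellFeatureMatrix, CellGraph, EmbeddingSet, MetricsReport
from .graph import GraphConfig, build_modality_graph
from .metrics import evaluate_integration, transfer_labels, umap_view
from .nn import EncoderModel, ModelConfig, init_model
from .preprocess import PreprocConfig, preprocess_matrix
from .train import TrainConfig, TrainTrace, embed, train


class GraphContrastiveIntegration:
    """Cross-modality graph contrastive integration of paired RNA/ATAC data.

    Parameters
    ----------
    rna, atac
        Paired matrices: identical cell ids in identical order.  The RNA
        matrix holds counts; the ATAC matrix holds gene-activity values.
    labels
        Optional per-cell type labels (RNA annotation used for transfer and
        evaluation).
    config
        Full pipeline configuration; defaults reproduce the published
        hyperparameters (lr 6e-4, PCA 30, k 20, hidden 300, tau 0.1).
    """

    def __init__(self, rna: CellFeatureMatrix, atac: CellFeatureMatrix,
                 labels: Optional[Sequence[str]] = None,
                 config: Optional[PipelineConfig] = None):
        if rna.cell_ids != atac.cell_ids:
            raise ValueError("rna and atac must share identical cell ids in identical order")
        if labels is not None and len(labels) != rna.n_cells:
            raise ValueError("labels length must equal the number of cells")
        self.rna = rna
        self.atac = atac
        self.labels = None if labels is None else [str(l) for l in labels]
        self.config = config if config is not None else PipelineConfig()

    @classmethod
    def from_dataframes(cls, rna_df: pd.DataFrame, atac_df: pd.DataFrame,
                        labels: Optional[Sequence[str]] = None,
                        config: Optional[PipelineConfig] = None) -> "GraphContrastiveIntegration":
        """Build from cells x features DataFrames (index = cell ids)."""
        rna = CellFeatureMatrix(rna_df.to_numpy(dtype=np.float64),
                                [str(c) for c in rna_df.index],
                                [str(c) for c in rna_df.columns], "RNA")
        atac = CellFeatureMatrix(atac_df.to_numpy(dtype=np.float64),
                                 [str(c) for c in atac_df.index],
                                 [str(c) for c in atac_df.columns], "ATAC")
        return cls(rna, atac, labels=labels, config=config)

    def fit(self, seed: Optional[int] = None, verbose: bool = False) -> "IntegrationResults":
        """Preprocess, build graphs, train, embed, transfer, evaluate."""
        cfg = self.config
        if seed is not None:
            cfg.graph.seed = seed
            cfg.model.seed = seed
            cfg.train.seed = seed

        x_r = preprocess_matrix(self.rna, cfg.preproc)
        x_a = preprocess_matrix(self.atac, cfg.preproc)
        if x_r.n_features != x_a.n_features:  # ragged PCA dims on tiny inputs
            d = min(x_r.n_features, x_a.n_features)
            x_r = x_r.copy_with(values=x_r.dense()[:, :d], feature_ids=x_r.feature_ids[:d])
            x_a = x_a.copy_with(values=x_a.dense()[:, :d], feature_ids=x_a.feature_ids[:d])
        if cfg.model.in_dim != x_r.n_features:
            cfg.model.in_dim = x_r.n_features

        g_r = build_modality_graph(x_r, cfg.graph)
        g_a = build_modality_graph(x_a, cfg.graph)

        model0 = init_model(cfg.model)
        model, trace = train(model0, g_r, g_a, x_r.dense(), x_a.dense(),
                             cfg.train, verbose=verbose)

        # The objective is cosine-based, so the integrated embedding lives on
        # the unit sphere: L2-normalize before any Euclidean downstream step.
        z_r = embed(model, g_r, x_r.dense())
        z_a = embed(model, g_a, x_a.dense())
        z_r = z_r / np.maximum(np.linalg.norm(z_r, axis=1, keepdims=True), 1e-12)
        z_a = z_a / np.maximum(np.linalg.norm(z_a, axis=1, keepdims=True), 1e-12)
        embeddings = EmbeddingSet(Z_R=z_r, Z_A=z_a, cell_ids=list(self.rna.cell_ids))

        predicted, report = None, None
        if self.labels is not None:
            report = evaluate_integration(
                embeddings, self.labels, self.labels,
                k_classify=cfg.eval.k_classify, k_be=cfg.eval.k_be,
                averaging=cfg.eval.averaging,
            )
            predicted = transfer_labels(z_r, self.labels, z_a, cfg.eval.k_classify)

        return IntegrationResults(
            model=model, trace=trace, embeddings=embeddings,
            graphs={"RNA": g_r, "ATAC": g_a},
            pca={"RNA": x_r, "ATAC": x_a},
            labels=self.labels, predicted_labels=predicted,
            metrics=report, config=cfg,
        )


@dataclass
class IntegrationResults:
    """Everything a fitted integration produced."""

    model: EncoderModel
    trace: TrainTrace
    embeddings: EmbeddingSet
    graphs: Dict[str, CellGraph]
    pca: Dict[str, CellFeatureMatrix]
    labels: Optional[List[str]]
    predicted_labels: Optional[List[str]]
    metrics: Optional[MetricsReport]
    config: PipelineConfig

    @property
    def final_loss(self) -> float:
        return self.trace.losses[-1]

    def summary(self) -> str:
        """Plain-text summary table of the fit and its evaluation."""
        c = self.config
        n = self.embeddings.n_cells
        lines = [
            "Graph Contrastive Multi-Omics Integration",
            "=" * 57,
            f"{'cells (paired)':<28}{n:>12}",
            f"{'encoder':<28}{c.model.encoder_kind:>12}",
            f"{'loss':<28}{c.train.loss_kind:>12}",
            f"{'epochs run':<28}{len(self.trace):>12}",
            f"{'parameters':<28}{self.model.n_parameters():>12}",
            f"{'final loss':<28}{self.final_loss:>12.5f}",
            f"{'final within-pair cosine':<28}{self.trace.pair_cosine[-1]:>12.4f}",
        ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                "-" * 57,
                f"{'ARI':<28}{m.ari:>12.4f}",
                f"{'NMI':<28}{m.nmi:>12.4f}",
                f"{'F1 (' + m.conventions.get('f1', 'macro') + ')':<28}{m.f1:>12.4f}",
                f"{'SUM':<28}{m.sum_score:>12.4f}",
                f"{'batch entropy':<28}{m.batch_entropy:>12.4f}",
                f"{'silhouette':<28}{m.silhouette:>12.4f}",
            ]
        lines.append("=" * 57)
        return "\n".join(lines)

    def umap(self, n_neighbors: int = 30, seed: int = 0) -> np.ndarray:
        """2-D UMAP layout of the joint embedding (visualization only)."""
        return umap_view(self.embeddings, n_neighbors=n_neighbors, seed=seed)

    def plot_umap(self, path: Optional[str] = None, n_neighbors: int = 30, seed: int = 0):
        """UMAP scatter colored by modality and (when known) by label."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        xy = self.umap(n_neighbors=n_neighbors, seed=seed)
        mod = self.embeddings.joint_modality
        n_panels = 2 if self.labels is not None else 1
        fig, axes = plt.subplots(1, n_panels, figsize=(6 * n_panels, 5), squeeze=False)
        for m, color in (("RNA", "tab:blue"), ("ATAC", "tab:orange")):
            sel = mod == m
            axes[0, 0].scatter(xy[sel, 0], xy[sel, 1], s=4, alpha=0.6, label=m, c=color)
        axes[0, 0].set_title("joint embedding by modality")
        axes[0, 0].legend()
        if self.labels is not None:
            joint_labels = np.array(self.labels + self.labels)
            for lab in np.unique(joint_labels):
                sel = joint_labels == lab
                axes[0, 1].scatter(xy[sel, 0], xy[sel, 1], s=4, alpha=0.6, label=lab)
            axes[0, 1].set_title("joint embedding by cell type")
            axes[0, 1].legend(markerscale=3, fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig
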