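"""End-to-end pipeline over on-disk inputs: the `run` command's engine.

Thin orchestration over :class:`GraphContrastiveIntegration`: read inputs,
fit, write every artifact (checkpoint, embeddings CSV, predicted labels,
metrics JSON, training log, replay log of seeds actually used), abort with
the failing stage's name on error.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Optional

from .config import PipelineConfig
from .io import read_labels, read_matrix, write_embeddings, write_labels
from .model import GraphContrastiveIntegration
from .nn import save_checkpoint


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, rna_path: str, atac_path: str,
                 labels_path: Optional[str] = None, verbose: bool = False) -> str:
    """Execute the full workflow; returns the artifacts directory."""
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise StageError(name, exc) from exc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rna = stage("read-rna", read_matrix, rna_path, "RNA")
        atac = stage("read-atac", read_matrix, atac_path, "ATAC")

    labels = None
    if labels_path is not None:
        ids, labs = stage("read-labels", read_labels, labels_path)
        if ids != rna.cell_ids:
            raise StageError("read-labels", ValueError("label cell ids do not match matrix"))
        labels = labs

    mdl = GraphContrastiveIntegration(rna, atac, labels=labels, config=cfg)
    res = stage("fit", mdl.fit, seed=cfg.seed, verbose=verbose)

    stage("write-checkpoint", save_checkpoint, res.model,
          os.path.join(outdir, "checkpoint.npz"))
    stage("write-embeddings", write_embeddings, res.embeddings,
          os.path.join(outdir, "embeddings.csv"))

    skipped = []
    if res.predicted_labels is not None:
        stage("write-predictions", write_labels, rna.cell_ids, res.predicted_labels,
              os.path.join(outdir, "predicted_labels.csv"))
    else:
        skipped.append("predicted_labels")
    if res.metrics is not None:
        with open(os.path.join(outdir, "metrics.json"), "w") as fh:
            json.dump(res.metrics.to_dict(), fh, indent=1, sort_keys=True)
    else:
        skipped.append("metrics")

    with open(os.path.join(outdir, "train_log.jsonl"), "w") as fh:
        for e, (l, pc, s) in enumerate(zip(res.trace.losses, res.trace.pair_cosine,
                                           res.trace.seconds)):
            fh.write(json.dumps({"epoch": e, "loss": round(l, 8),
                                 "pair_cosine": round(pc, 8), "seconds": round(s, 4)}) + "\n")

    replay = {
        "seed": cfg.seed,
        "graph_seed": cfg.graph.seed,
        "model_seed": cfg.model.seed,
        "train_seed": cfg.train.seed,
        "skipped": skipped,
        "summary": res.summary(),
    }
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(replay, fh, indent=1, sort_keys=True)
    return outdir
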