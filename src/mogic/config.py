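"""Pipeline configuration: a YAML document with one section per stage.

An empty document yields the full defaults (lr 0.0006, PCA 30, k 20, hidden
300, tau 0.1).  Unknown keys are rejected by name; a global ``seed``
overrides any section seed that was not set explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Any, Dict, Optional

import yaml

from .graph import GraphConfig
from .nn import ModelConfig
from .preprocess import PreprocConfig
from .train import TrainConfig


@dataclass
class EvalConfig:
    k_classify: int = 30
    k_be: int = 15
    averaging: str = "macro"

    def __post_init__(self) -> None:
        if self.k_classify < 1 or self.k_be < 1:
            raise ValueError("k_classify and k_be must be >= 1")
        if self.averaging not in ("macro", "weighted"):
            raise ValueError("averaging must be 'macro' or 'weighted'")


@dataclass
class PipelineConfig:
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    outdir: str = "mogic_out"


_SECTIONS = {
    "preproc": PreprocConfig,
    "graph": GraphConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "eval": EvalConfig,
}
_GLOBAL_KEYS = {"seed", "outdir"}


def _build_section(name: str, cls, raw: Dict[str, Any]):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    try:
        return cls(**raw), set(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in section '{name}': {exc}") from exc


def validate_config(raw_config_text: str) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; empty text -> all defaults."""
    doc = yaml.safe_load(raw_config_text) if raw_config_text.strip() else {}
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping of sections")

    unknown = set(doc) - set(_SECTIONS) - _GLOBAL_KEYS
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    sections: Dict[str, Any] = {}
    explicit_seeds: Dict[str, bool] = {}
    for name, cls in _SECTIONS.items():
        raw = doc.get(name, {}) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"section '{name}' must be a mapping")
        sections[name], set_keys = _build_section(name, cls, raw)
        explicit_seeds[name] = "seed" in set_keys

    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError(f"seed: expected integer, got {seed!r}")
    cfg = PipelineConfig(seed=seed, outdir=str(doc.get("outdir", "mogic_out")), **sections)

    # global seed overrides section seeds left unset
    for name in ("graph", "model", "train"):
        if not explicit_seeds[name]:
            getattr(cfg, name).seed = seed
    # model.in_dim follows the PCA dimension unless pinned explicitly
    if "in_dim" not in (doc.get("model") or {}):
        cfg.model.in_dim = cfg.preproc.n_pca
    # train.tau follows model.tau unless pinned
    if "tau" not in (doc.get("train") or {}):
        cfg.train.tau = cfg.model.tau
    return cfg
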