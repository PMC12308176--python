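import warnings

import numpy as np
import pytest

from mogic import (GraphContrastiveIntegration, PipelineConfig, SimConfig,
                   simulate_paired)


@pytest.fixture(autouse=True)
def _quiet_io_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny paired dataset for fast unit tests."""
    return simulate_paired(SimConfig(n_cells=150, n_genes=80, n_markers_per_type=5, seed=7))


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The 600-cell, 3-type, 200-gene reference dataset (seed 1)."""
    return simulate_paired(SimConfig(seed=1))


def fit_reference(ds, seed, encoder_kind="GCN", epochs=300):
    cfg = PipelineConfig()
    cfg.train.epochs = epochs
    cfg.model.encoder_kind = encoder_kind
    model = GraphContrastiveIntegration(ds.rna, ds.atac, labels=ds.labels, config=cfg)
    return model.fit(seed=seed)


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_dataset):
    """One 300-epoch GCN fit on the reference dataset (seed 1); shared across tests."""
    return fit_reference(benchmark_dataset, seed=1)
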