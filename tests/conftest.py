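"""Shared fixtures: scaled-down simulated datasets and pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from ccpls import Config, SimulationSpec, run_ccpls, simulate_dataset


def processed_scale_config(seed: int, n_perm: int = 99) -> Config:
    """Config for data simulated directly on the processed scale."""
    cfg = Config(seed=seed, normalize="center", cell_types=["A"])
    cfg.hvg.method = "all"
    cfg.filter.n_perm = n_perm
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down baseline simulation: 260 cells, 4x60 genes, w_max=1, alpha=1."""
    spec = SimulationSpec(n_cells=260, genes_per_cluster=60, seed=11)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_run(small_sim):
    ds, _ = small_sim
    return run_ccpls(ds, processed_scale_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
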