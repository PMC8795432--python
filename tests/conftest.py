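"""Shared fixtures: one paired simulated dataset reused across test modules."""

import numpy as np
import pytest

from dlnatlas import simdata


@pytest.fixture(scope="session")
def default_sim():
    """Default study-condition simulation (10 types, 3 timepoints, 2 stimuli)."""
    config = simdata.default_config(seed=5)
    rna, truth = simdata.simulate_rna(config)
    return config, rna, truth


@pytest.fixture(scope="session")
def paired_sim(default_sim):
    """The matching ATAC side of the default simulation."""
    config, rna, truth = default_sim
    atac, peaks, (hits, motif_names), truth = simdata.simulate_atac(config, truth)
    return config, rna, atac, peaks, hits, motif_names, truth


@pytest.fixture(scope="session")
def de_sim():
    """One cell type, 500 cells/side, planted logFC-1.5 ISG program."""
    config = simdata.default_config(
        seed=2, n_cell_types=1, cells_per_type_per_condition=500, n_genes=600,
        timepoints=("day0", "day1"), stimuli=("3M",), doublet_rate=0.0,
        mito_high_fraction=0.0,
    )
    rna, truth = simdata.simulate_rna(config)
    return config, rna, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
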