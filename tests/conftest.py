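import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sdrkit.simulator import SimulationConfig, simulate_cells, synthesize_reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_run():
    """Small zero-error, zero-ambient simulated run with 5% doublets."""
    cfg = SimulationConfig(
        n_cells=40, n_samples=3, doublet_rate=0.05, seed=11,
        mean_gdna_reads_per_amplicon=12, mean_rna_molecules_per_gene=3,
    )
    truth = simulate_cells(cfg)
    reads = synthesize_reads(truth, cfg)
    return cfg, truth, reads


@pytest.fixture(scope="session")
def noisy_run():
    """Small run with realistic error rates, ambient reads, dropout and
    genotype noise."""
    cfg = SimulationConfig(
        n_cells=50, n_samples=3, doublet_rate=0.05, seed=13,
        sub_rate=0.005, ins_rate=0.0005, del_rate=0.0005,
        ambient_fraction=0.01, ado_rate=0.10, noise_rate=0.001,
    )
    truth = simulate_cells(cfg)
    reads = synthesize_reads(truth, cfg)
    return cfg, truth, reads
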