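import numpy as np
import pandas as pd
import pytest

from hybridexpr.simulate import SimConfig, simulate_ase, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """Small seeded count simulation shared across tests."""
    cfg = SimConfig(n_genes=300, seed=42, dispersion=0.0)
    counts, design, truth = simulate_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def small_ase_sim():
    cfg = SimConfig(n_genes=300, seed=42, site_coverage_mean=120.0)
    snps, truth = simulate_ase(cfg)
    return cfg, snps, truth


@pytest.fixture
def toy_counts():
    """Hand-sized count matrix: 4 genes x 6 samples (3 genotypes x 2 reps)."""
    rng = np.random.default_rng(0)
    genes = ["gA", "gB", "gC", "gD"]
    samples = ["P1_r1", "P1_r2", "P2_r1", "P2_r2", "F1_r1", "F1_r2"]
    counts = pd.DataFrame(
        rng.poisson(200, size=(4, 6)), index=genes, columns=samples
    )
    design = pd.DataFrame(
        {
            "genotype": ["P1", "P1", "P2", "P2", "F1", "F1"],
            "replicate": [1, 2, 1, 2, 1, 2],
        },
        index=samples,
    )
    lengths = pd.Series([1000, 2000, 500, 4000], index=genes)
    return counts, design, lengths
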