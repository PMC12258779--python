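import numpy as np
import pytest

from ppgsxe.config import SimConfig
from ppgsxe.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully featured cohort shared by read-only tests."""
    cfg = SimConfig(
        n_individuals=600, n_chromosomes=2, n_blocks_per_chrom=4,
        variants_per_block=10, ld_rho=0.7, n_genes=16, n_pathways=8,
        genes_per_pathway=2, causal_pathways=("PWY_001",),
        h2_main=0.3, var_gxe=0.05, alpha_E=0.1, n_pcs=2, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
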