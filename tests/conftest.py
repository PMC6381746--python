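import numpy as np
import pytest

from bayeswin import sim


@pytest.fixture(scope="session")
def small_panel():
    """A clean simulated panel shared by QC/window tests (no missingness)."""
    cfg = sim.SimConfig(
        n_animals=400,
        chrom_lengths_bp=(8_000_000, 8_000_000),
        snps_per_chrom=(120, 120),
        n_qtl=8,
        seed=11,
    )
    G, snp_map = sim.simulate_genotypes(cfg)
    alpha = sim.simulate_qtl_effects(G, cfg)
    return cfg, G, snp_map, alpha


@pytest.fixture(scope="session")
def phenotyped_panel(small_panel):
    cfg, G, snp_map, alpha = small_panel
    pheno = sim.simulate_ordinal_phenotypes(G, alpha, cfg)
    return cfg, G, snp_map, alpha, pheno


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
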