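import numpy as np
import pytest

from cbsdgs import simdata


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale two-panel config used across unit tests."""
    return simdata.SimConfig(
        n_clones_panel1=60, n_clones_panel2=60, markers_per_chrom=200,
        background_n=50, ai_fraction=0.5, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    geno, truth = simdata.simulate_genotypes(small_cfg)
    return geno, truth


@pytest.fixture(scope="session")
def small_pheno(small_cfg, small_sim):
    geno, truth = small_sim
    return simdata.simulate_phenotypes(geno, truth, small_cfg)


@pytest.fixture(scope="session")
def medium_sim():
    """Larger panel for GWAS / prediction behaviour tests."""
    cfg = simdata.SimConfig(
        n_clones_panel1=150, n_clones_panel2=150, markers_per_chrom=300,
        background_n=80, ai_fraction=0.4, seed=7)
    geno, truth = simdata.simulate_genotypes(cfg)
    return cfg, geno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
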