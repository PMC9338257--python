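"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pytest

import cottongp as cg


@pytest.fixture(scope="session")
def panel_study():
    """Diverse 400-line panel (100 F1 families x 4 from 80 founders), one
    polygenic trait with h2 = 0.5 and no environment terms."""
    cfg = cg.SimConfig(
        n_founders=80,
        n_families=100,
        offspring_per_family=4,
        selfing_generations=0,
        n_markers=1000,
        n_chromosomes=20,
        n_years=1,
        experiments_per_year=1,
        seed=42,
        traits={
            "t": cg.TraitConfig(
                n_qtl=300, h2=0.5, year_share=0.0, experiment_share=0.0
            )
        },
    )
    return cg.simulate_study(cfg)


@pytest.fixture(scope="session")
def panel_geno(panel_study):
    return cg.filter_markers(panel_study.genotypes, 0.0, 0.025)


@pytest.fixture(scope="session")
def panel_grm(panel_geno):
    return cg.compute_grm(panel_geno)


@pytest.fixture(scope="session")
def panel_data(panel_study, panel_geno, panel_grm):
    return cg.ModelData.from_tables(
        panel_study.phenotypes, "t", genotypes=panel_geno, G=panel_grm
    )


@pytest.fixture(scope="session")
def multiyear_study():
    """Small breeding program with 3 years x 2 experiments, family turnover
    and year/experiment variance, F2-selfed lines with a real pedigree."""
    cfg = cg.SimConfig(
        n_founders=30,
        n_families=12,
        offspring_per_family=10,
        selfing_generations=2,
        n_markers=400,
        n_chromosomes=26,
        n_years=3,
        experiments_per_year=2,
        seed=7,
        traits={
            "t": cg.TraitConfig(
                n_qtl=100, h2=0.4, year_share=0.15, experiment_share=0.05
            )
        },
    )
    return cg.simulate_study(cfg)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Very short chain for smoke tests that only exercise plumbing."""
    return cg.MCMCSettings(n_iter=400, burn_in=100, thin=3, seed=5)


@pytest.fixture(scope="session")
def reduced_mcmc():
    return cg.MCMCSettings.reduced(seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
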