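"""Shared fixtures: one small synthetic study reused across test modules."""

import pytest

from trmet.config import SimulationConfig
from trmet import quantify, synthdata


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 20 lines, 120 ions, 30 TRs, 300 genes."""
    return SimulationConfig(
        n_cell_lines=20, n_tissues=4, n_ions=120, n_true_metabolites=80,
        n_genes=300, n_trs=30, n_kinases=6, n_coupled_trs=5,
        n_volume_ions=15, seed=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthdata.simulate_study(small_config)


@pytest.fixture(scope="session")
def noiseless_study():
    # isolates the quantification chain: no planted couplings or tissue
    # shifts, and enough lines / bio variation that the r > 0.8 selection
    # separates volume reporters exactly (as it does at full study size)
    cfg = SimulationConfig(
        n_cell_lines=24, n_tissues=4, n_ions=60, n_true_metabolites=40,
        n_genes=150, n_trs=15, n_kinases=4, n_coupled_trs=0,
        n_volume_ions=12, noise_cv=0.0, tissue_effect_sd=0.0,
        bio_variation_sd=1.0, seed=5,
    )
    return synthdata.simulate_study(cfg)


@pytest.fixture(scope="session")
def quantified(small_study):
    """(AbundanceMatrix, ZMatrix, PlateFactors) for the small study."""
    return quantify.quantify(small_study.intensities, small_study.counts)
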