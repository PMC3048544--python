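"""Shared fixtures: a small synthetic experiment generated once per session."""

import logging

import pytest

from tauvar import simulate
from tauvar.models import SimulationConfig

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        chromosome_lengths=[300_000],
        n_genes=6,
        n_variants_per_category=8,
        mean_depth=25.0,
        error_rate=0.0,
        n_background_sites=300,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(ref, genes, truth) for the small session experiment."""
    ref = simulate.generate_reference(small_config)
    genes = simulate.generate_gene_models(ref, small_config)
    truth = simulate.plant_variants(ref, genes, small_config)
    return ref, genes, truth


@pytest.fixture(scope="session")
def small_pileup(small_config, small_world):
    ref, _genes, truth = small_world
    return simulate.simulate_pileup(ref, truth, small_config)
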