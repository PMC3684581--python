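"""Shared fixtures: small synthetic grids and virtual-species data.

Everything is generated in memory from fixed seeds; no data files ship
with the tests.
"""

import numpy as np
import pytest

import nichecast as nc


@pytest.fixture(scope="session")
def grid():
    """Default-scale environmental grid (100x100, 4 vars + decoy)."""
    return nc.make_env_layers(100, 100, 4, 0.9, seed=3)


@pytest.fixture(scope="session")
def species_config():
    return nc.VirtualSpeciesConfig(seed=3)


@pytest.fixture(scope="session")
def suitability(grid, species_config):
    return nc.true_suitability(grid, species_config)


@pytest.fixture(scope="session")
def presences(suitability):
    return nc.sample_presences(suitability, 300, seed=4, taxon="species")


@pytest.fixture(scope="session")
def background(grid):
    return nc.sample_background(grid, 5000, seed=5)


@pytest.fixture(scope="session")
def table(grid, presences, background):
    """Weighted presence/background training table at 50% prevalence."""
    return nc.build_training_table(grid, presences, background, phi=0.5)


@pytest.fixture(scope="session")
def small_grid():
    """Cheap 40x40 grid for pipeline-level tests."""
    return nc.make_env_layers(40, 40, 3, 0.9, seed=11)
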