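"""Shared fixtures: everything is generated programmatically and seeded."""
import numpy as np
import pytest

from boxcc import (default_table, generate_structure, simulate_observed_map,
                   synthesize_map, suggest_grid)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def small_structure():
    """Six-residue idealized helix in a padded P1 cell."""
    return generate_structure(6, seed=3)


@pytest.fixture(scope="session")
def obs_map(small_structure):
    """Simulated observed map at 1.8 A with reflection noise."""
    return simulate_observed_map(small_structure, 1.8, noise_sigma=0.05, seed=5)


@pytest.fixture(scope="session")
def selfconsistent_map(small_structure):
    """Map synthesized with the same B=2 policy as the calculated density."""
    return synthesize_map(small_structure, suggest_grid(small_structure.cell, 0.3),
                          b_override=2.0)


@pytest.fixture(scope="session")
def dipeptide():
    return generate_structure(2, composition=("GLY", "ALA"), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
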