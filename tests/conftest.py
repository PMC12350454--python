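"""Shared fixtures: toy complexes and pre-simulated trajectories.

The expensive statistical fixtures (the 5e4-frame double-well walk and
the 5000-frame block-correlated run) are session-scoped so every test
that interrogates them shares one realization at a fixed seed.
"""

import numpy as np
import pytest

from bindscape import build_toy_complex, select
from bindscape.synthetic import (
    ToySpec,
    simulate_block_correlated,
    simulate_two_basin,
)

TWO_BASIN_SEED = 42
BLOCK_SEED = 7


@pytest.fixture(scope="session")
def two_basin_50k():
    """Long double-well run used for Boltzmann-recovery checks."""
    spec = ToySpec(seed=TWO_BASIN_SEED, n_frames=50_000, barrier_kcal=3.0,
                   temperature_K=310.0)
    trajectory, cv, truth = simulate_two_basin(spec)
    return spec, trajectory, cv, truth


@pytest.fixture(scope="session")
def block_5k():
    """Block-correlated run (rho_in 0.9 / rho_out 0.0) for DCCM recovery."""
    spec = ToySpec(seed=BLOCK_SEED, n_frames=5000, rho_intra=0.9, rho_inter=0.0)
    trajectory = simulate_block_correlated(spec)
    topology, reference, doc = build_toy_complex(spec)
    protein = select(topology, "segment:protein")
    return spec, trajectory, topology, protein


@pytest.fixture()
def toy_complex():
    spec = ToySpec(seed=5)
    topology, reference, doc = build_toy_complex(spec)
    return spec, topology, reference, doc


@pytest.fixture()
def toy_short_run():
    spec = ToySpec(seed=5, n_frames=120)
    trajectory, cv, truth = simulate_two_basin(spec)
    topology, reference, doc = build_toy_complex(spec)
    return spec, topology, trajectory


def block_structure(spec: ToySpec, n_sites: int) -> np.ndarray:
    """Block label per site, mirroring the generator's contiguous split."""
    edges = np.linspace(0, n_sites, spec.n_blocks + 1).astype(int)
    return np.repeat(np.arange(spec.n_blocks), np.diff(edges))
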