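"""Shared fixtures: small grids and solved policies reused across test modules."""

import numpy as np
import pytest

import cdac
from cdac.inference import GridDynamics, build_belief_grid


@pytest.fixture(scope="session")
def grid3():
    """Coarse k=3 grid for fast unit tests."""
    return build_belief_grid(3, 60)


@pytest.fixture(scope="session")
def grid3_fine():
    """Full-resolution k=3 grid (201 points per edge)."""
    return build_belief_grid(3, 200)


@pytest.fixture(scope="session")
def model9():
    return cdac.ObservationModel(3, 0.9)


@pytest.fixture(scope="session")
def model68():
    return cdac.ObservationModel(3, 0.68)


@pytest.fixture(scope="session")
def dyn3(grid3, model9):
    return GridDynamics(grid3, model9)


@pytest.fixture(scope="session")
def solved_cs0(grid3, model9, dyn3):
    return cdac.solve_cdac(model9, cdac.CostParams(0.1, 0.0), grid3, dynamics=dyn3)


@pytest.fixture(scope="session")
def solved_cs1(grid3, model9, dyn3):
    return cdac.solve_cdac(model9, cdac.CostParams(0.1, 0.1), grid3, dynamics=dyn3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
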