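"""Shared fixtures: coarse-grid solves reused across solver and mapping tests."""

import pytest

from ectplan import (
    SimulationGrid,
    build_array,
    compare_arrays,
    solve_potential,
)


@pytest.fixture(scope="session")
def coarse_grid():
    """40 mm domain at 0.1 mm spacing: fast but fine enough for every guard."""
    return SimulationGrid.centered(40.0, 0.1)


@pytest.fixture(scope="session")
def standard_array():
    return build_array("standard")


@pytest.fixture(scope="session")
def thin_array():
    return build_array("thin")


@pytest.fixture(scope="session")
def standard_solution(standard_array, coarse_grid):
    return solve_potential(standard_array, 0.2, coarse_grid, 400.0)


@pytest.fixture(scope="session")
def coarse_comparison(standard_array, thin_array, coarse_grid):
    return compare_arrays(standard_array, thin_array, 0.2, coarse_grid, 400.0)
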