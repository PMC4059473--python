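"""Shared fixtures: small, fast model instances and their eigenpairs.

Grids keep the ratio n_cells = 3 * (n_nodes - 1) so that the delay-matched
time step sits at ~0.9 of the transport stability bound for the preset
growth speeds.
"""

import numpy as np
import pytest

from stagepop import (
    adjoint_eigenfunctions,
    make_example_model,
    malthusian_parameter,
)


@pytest.fixture(scope="session")
def generic_small():
    return make_example_model("generic", n_cells=48, n_nodes=17)


@pytest.fixture(scope="session")
def generic_eigen(generic_small):
    return malthusian_parameter(generic_small)


@pytest.fixture(scope="session")
def generic_adjoint(generic_small, generic_eigen):
    return adjoint_eigenfunctions(generic_small, generic_eigen)


@pytest.fixture(scope="session")
def symmetric_small():
    return make_example_model("symmetric", n_cells=48, n_nodes=17)


@pytest.fixture(scope="session")
def equal_growth_small():
    return make_example_model("equal-growth", n_cells=48, n_nodes=17)


@pytest.fixture(scope="session")
def equal_growth_eigen(equal_growth_small):
    return malthusian_parameter(equal_growth_small)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
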