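"""Shared session fixtures: response states and quadrature grids are expensive
enough (SCF + CPHF + integral builds) that each is built once per session."""

import numpy as np
import pytest

from ctocd.becke import molecular_grid
from ctocd.fixtures import make_fixture
from ctocd.molecule import perceive_bonds
from ctocd.response import build_response_state


@pytest.fixture(scope="session")
def he_mol():
    return make_fixture("He")


@pytest.fixture(scope="session")
def h2o_mol():
    return perceive_bonds(make_fixture("H2O"))


@pytest.fixture(scope="session")
def he_state(he_mol):
    return build_response_state(he_mol, "sto-3g")


@pytest.fixture(scope="session")
def he_state_etsp(he_mol):
    """He in the matched s/p even-tempered basis (good momentum response)."""
    return build_response_state(he_mol, "et-sp")


@pytest.fixture(scope="session")
def h2o_state(h2o_mol):
    return build_response_state(h2o_mol, "sto-3g")


@pytest.fixture(scope="session")
def ch4_state():
    return build_response_state(perceive_bonds(make_fixture("CH4")), "sto-3g")


@pytest.fixture(scope="session")
def he_grid(he_mol):
    return molecular_grid(he_mol)


@pytest.fixture(scope="session")
def h2o_grid(h2o_mol):
    return molecular_grid(h2o_mol)


@pytest.fixture(scope="session")
def ch4_grid(ch4_state):
    return molecular_grid(ch4_state.molecule)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230323)
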