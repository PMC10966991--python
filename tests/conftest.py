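import numpy as np
import pytest

from diffmd import forcefield as ff
from diffmd import synthetic as syn


@pytest.fixture(scope="session")
def registry():
    vec, reg = ff.build_default_registry()
    return vec, reg


@pytest.fixture(scope="session")
def default_vector(registry):
    return registry[0]


@pytest.fixture(scope="session")
def tripeptide(registry):
    """3-residue polyalanine with parameters applied (33 atoms)."""
    vec, reg = registry
    _, system = syn.make_toy_chain(syn.ToySpec(3, "extended"), reg)
    return ff.apply_parameter_vector(vec, system)


@pytest.fixture(scope="session")
def pentapeptide(registry):
    vec, reg = registry
    _, system = syn.make_toy_chain(syn.ToySpec(5, "helical"), reg)
    return ff.apply_parameter_vector(vec, system)


@pytest.fixture(scope="session")
def ethane(registry):
    """8-atom ethane-like toy built from an explicit bond graph."""
    from diffmd import topology as topo
    vec, reg = registry
    coords = np.array([
        [0.00, 0.00, 0.00], [0.04, 0.10, 0.00], [0.04, -0.05, 0.09],
        [0.04, -0.05, -0.09], [-0.153, 0.00, 0.00], [-0.193, -0.10, 0.00],
        [-0.193, 0.05, 0.09], [-0.193, 0.05, -0.09]])
    types = ["CT", "HC", "HC", "HC", "CT", "HC", "HC", "HC"]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5), (4, 6), (4, 7)]
    charges = np.array([-0.09, 0.03, 0.03, 0.03, -0.09, 0.03, 0.03, 0.03])
    system = topo.system_from_bond_graph(types, bonds, coords, reg,
                                         charges=charges)
    return ff.apply_parameter_vector(vec, system)
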