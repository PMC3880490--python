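import numpy as np
import pytest

from fragsig.chemio import Atom, Molecule, assign_radii
from fragsig.fixtures import make_box_mesh, make_sphere_mesh, make_toy_molecule


@pytest.fixture(scope="session")
def benzene():
    return make_toy_molecule("benzene")


@pytest.fixture(scope="session")
def diphenylethane():
    return make_toy_molecule("diphenylethane")


@pytest.fixture(scope="session")
def single_carbon():
    mol = Molecule("C1", [Atom(0, "C", np.zeros(3), partial_charge=1.0)], [])
    return assign_radii(mol)


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    return make_sphere_mesh(1.0, subdivisions=3)


@pytest.fixture(scope="session")
def box_mesh():
    return make_box_mesh(10.0, resolution=4)
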