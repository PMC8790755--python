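import numpy as np
import pytest

from voxattrib.structio import AtomRecord, ComplexStructure, vdw_radius
from voxattrib.synthcomplex import generate_complex, make_clashed_pose
from voxattrib.voxelizer import voxelize


@pytest.fixture(scope="session")
def small_complex():
    return generate_complex(11)


@pytest.fixture(scope="session")
def small_clashed(small_complex):
    posed, label = make_clashed_pose(small_complex, 12)
    return posed, label


@pytest.fixture(scope="session")
def small_grid(small_complex):
    return voxelize(small_complex)


def make_atom(element="C", position=(0.0, 0.0, 0.0), source="ligand", **flags):
    flags.setdefault("heavy", element != "H")
    return AtomRecord(element=element, position=np.array(position, dtype=float),
                      source=source, vdw_radius=vdw_radius(element), **flags)


@pytest.fixture
def tiny_complex():
    """One protein atom 3 Å from a two-atom ligand."""
    ligand = [make_atom("C", (0, 0, 0), hydrophobic=True),
              make_atom("O", (1.5, 0, 0), acceptor=True)]
    protein = [make_atom("N", (0, 3.0, 0), source="protein", donor=True)]
    return ComplexStructure(protein, ligand, "tiny")
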