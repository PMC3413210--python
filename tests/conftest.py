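import numpy as np
import pytest

from clashaudit.fixtures import FixtureSpec, build_ideal_peptide, contact_scene
from clashaudit.hydrogen_placement import place_riding_hydrogens
from clashaudit.structure_model import (
    AtomRecord, ResidueUnit, StructureModel, build_covalent_graph,
)


@pytest.fixture(scope="session")
def polyala20():
    """Ideal 20-residue polyalanine helix, heavy atoms only."""
    return build_ideal_peptide(FixtureSpec("A" * 20))


@pytest.fixture(scope="session")
def polyala20_h(polyala20):
    model = polyala20.copy()
    place_riding_hydrogens(model)
    return model


@pytest.fixture(scope="session")
def scene50():
    """50 residues with one clash (ratio 0.75) and one severe (0.65)."""
    return contact_scene(50, [0.75, 0.65])


def make_point_model(coords, element="C"):
    """Bare model wrapping a coordinate array (for contact-search tests)."""
    res = ResidueUnit("A", 1, "", "UNX")
    for i, c in enumerate(np.asarray(coords, float)):
        res.atoms.append(AtomRecord(serial=i + 1, name=f"X{i}", element=element,
                                    coords=c))
    return StructureModel([res])


@pytest.fixture
def point_model_factory():
    return make_point_model


def write_pdb(tmp_path, text, name="input.pdb"):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


@pytest.fixture
def pdb_writer(tmp_path):
    return lambda text, name="input.pdb": write_pdb(tmp_path, text, name)
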