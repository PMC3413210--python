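import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clashaudit.fixtures import FixtureSpec, build_ideal_peptide
from clashaudit.hydrogen_placement import place_riding_hydrogens
from clashaudit.structure_model import (
    AtomRecord, EmptyInputError, FormatError, ResidueUnit, StructureModel,
    build_covalent_graph, read_structure, residue_count,
    select_primary_altlocs, write_structure,
)

SINGLE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
    "END\n"
)

TWO_MODEL_PDB = (
    "MODEL        1\n"
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
    "ENDMDL\n"
    "MODEL        2\n"
    "ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00 10.00           C\n"
    "ATOM      2  CB  ALA A   1       8.000   9.000   9.000  1.00 10.00           C\n"
    "ENDMDL\nEND\n"
)

ALTLOC_PDB = (
    "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N\n"
    "ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00 10.00           C\n"
    "ATOM      3  CB  SER A   1       2.000   1.400   0.000  1.00 10.00           C\n"
    "ATOM      4  OG ASER A   1       3.400   1.400   0.000  0.60 10.00           O\n"
    "ATOM      5  OG BSER A   1       2.000   1.400   1.400  0.40 10.00           O\n"
    "END\n"
)


class TestReadStructure:
    def test_single_atom(self, pdb_writer):
        model = read_structure(pdb_writer(SINGLE_ATOM_PDB))
        assert model.n_atoms() == 1
        assert len(model.residues) == 1
        np.testing.assert_allclose(model.atoms()[0].coords, [1.0, 2.0, 3.0])

    def test_first_model_only(self, pdb_writer):
        model = read_structure(pdb_writer(TWO_MODEL_PDB))
        assert model.n_atoms() == 1
        np.testing.assert_allclose(model.atoms()[0].coords, [1.0, 2.0, 3.0])

    def test_unparseable_raises(self, pdb_writer):
        with pytest.raises(FormatError):
            read_structure(pdb_writer("this is not a structure file\n", "x.cif"))

    def test_empty_raises(self, pdb_writer):
        with pytest.raises((FormatError, EmptyInputError)):
            read_structure(pdb_writer("END\n"))

    def test_pdb_and_mmcif_agree(self, tmp_path):
        model = build_ideal_peptide(FixtureSpec("ASA"))
        p_pdb, p_cif = str(tmp_path / "m.pdb"), str(tmp_path / "m.cif")
        write_structure(model, p_pdb)
        write_structure(model, p_cif)
        m1, m2 = read_structure(p_pdb), read_structure(p_cif)
        assert m1.n_atoms() == m2.n_atoms() == model.n_atoms()
        np.testing.assert_allclose(m1.coords(), m2.coords(), atol=1e-3)


class TestRoundTrip:
    def test_coordinates_preserved(self, tmp_path, polyala20_h):
        path = str(tmp_path / "rt.pdb")
        write_structure(polyala20_h, path)
        back = read_structure(path)
        assert back.n_atoms() == polyala20_h.n_atoms()
        assert [a.name for a in back.atoms()] == [a.name for a in polyala20_h.atoms()]
        np.testing.assert_allclose(back.coords(), polyala20_h.coords(), atol=1e-3)

    def test_hydrogen_element_column(self, tmp_path, polyala20_h):
        path = str(tmp_path / "h.pdb")
        write_structure(polyala20_h, path)
        h_lines = [ln for ln in open(path) if ln.startswith("ATOM")
                   and ln[12:16].strip().startswith("H")]
        assert h_lines
        assert all(ln[76:78].strip() == "H" for ln in h_lines)

    def test_long_atom_name_rejected(self, tmp_path):
        res = ResidueUnit("A", 1, "", "LIG")
        res.atoms.append(AtomRecord(serial=1, name="ABCDE", element="C",
                                    coords=[0, 0, 0]))
        with pytest.raises(ValueError, match="too long"):
            write_structure(StructureModel([res]), str(tmp_path / "x.pdb"))

    def test_serial_overflow_requires_hybrid36(self, tmp_path):
        res = ResidueUnit("A", 1, "", "UNX")
        res.atoms = [AtomRecord(serial=i, name="C", element="C", coords=[i * 0.1, 0, 0])
                     for i in range(100_001)]
        model = StructureModel([res])
        with pytest.raises(ValueError, match="hybrid36|mmCIF"):
            write_structure(model, str(tmp_path / "big.pdb"))


class TestAltlocs:
    def test_higher_occupancy_kept(self, pdb_writer):
        model = read_structure(pdb_writer(ALTLOC_PDB))
        out = select_primary_altlocs(model)
        ogs = out.residues[0].get_atoms("OG")
        assert len(ogs) == 1 and ogs[0].altloc == "A"

    def test_no_altlocs_unchanged(self, polyala20):
        out = select_primary_altlocs(polyala20)
        assert out.n_atoms() == polyala20.n_atoms()
        np.testing.assert_allclose(out.coords(), polyala20.coords())

    def test_tie_keeps_first(self, pdb_writer):
        text = ALTLOC_PDB.replace("0.60", "0.50").replace("0.40", "0.50")
        out = select_primary_altlocs(read_structure(pdb_writer(text)))
        assert out.residues[0].get_atoms("OG")[0].altloc == "A"

    def test_idempotent_and_never_grows(self, pdb_writer):
        model = read_structure(pdb_writer(ALTLOC_PDB))
        once = select_primary_altlocs(model)
        twice = select_primary_altlocs(once)
        assert once.n_atoms() <= model.n_atoms()
        assert twice.n_atoms() == once.n_atoms()

    @given(occ_a=st.floats(0.01, 1.0), occ_b=st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_selected_occupancy_is_max(self, occ_a, occ_b):
        res = ResidueUnit("A", 1, "", "SER", is_polymer=True)
        for alt, occ in (("A", occ_a), ("B", occ_b)):
            res.atoms.append(AtomRecord(serial=1, name="OG", element="O",
                                        coords=[0, 0, 0], occupancy=occ, altloc=alt))
        out = select_primary_altlocs(StructureModel([res]))
        kept = out.residues[0].get_atoms("OG")
        assert len(kept) == 1
        assert kept[0].occupancy == max(occ_a, occ_b) or occ_a == occ_b


class TestCovalentGraph:
    def test_peptide_bond(self):
        model = build_ideal_peptide(FixtureSpec("GA"))
        c = model.residues[0].get_atom("C")
        n = model.residues[1].get_atom("N")
        assert frozenset((c.index, n.index)) in model.bonds

    def test_disulfide(self):
        model = build_ideal_peptide(FixtureSpec("C"))
        res2 = ResidueUnit("B", 1, "", "CYS", is_polymer=True)
        sg1 = model.residues[0].get_atom("SG")
        for atom in model.residues[0].atoms:
            res2.atoms.append(AtomRecord(serial=0, name=atom.name, element=atom.element,
                                         coords=atom.coords + np.array([2.03, 0, 0])
                                         if atom.name == "SG"
                                         else atom.coords + np.array([6.0, 0, 0])))
        model.residues.append(res2)
        model.reindex()
        build_covalent_graph(model)
        sg2 = res2.get_atom("SG")
        assert frozenset((sg1.index, sg2.index)) in model.bonds

    def test_distance_fallback_for_ligand(self):
        res = ResidueUnit("A", 1, "", "LIG")
        res.atoms = [AtomRecord(serial=1, name="C1", element="C", coords=[0, 0, 0]),
                     AtomRecord(serial=2, name="C2", element="C", coords=[1.53, 0, 0])]
        model = StructureModel([res])
        build_covalent_graph(model)
        assert len(model.bonds) == 1

    def test_hydrogen_degree_is_one(self, polyala20_h):
        for atom in polyala20_h.atoms():
            if atom.is_hydrogen:
                assert len(polyala20_h.bonded(atom.index)) == 1

    def test_graph_symmetric(self, polyala20_h):
        for i, nbrs in polyala20_h.adjacency.items():
            for j in nbrs:
                assert i in polyala20_h.adjacency[j]


class TestResidueCount:
    def test_waters_excluded(self, polyala20):
        model = polyala20.copy()
        for k in range(30):
            res = ResidueUnit("W", k + 1, "", "HOH", is_water=True)
            res.atoms.append(AtomRecord(serial=0, name="O", element="O",
                                        coords=[50.0 + k, 0, 0]))
            model.residues.append(res)
        model.reindex()
        assert residue_count(model) == 20

    def test_two_chains_additive(self):
        m1 = build_ideal_peptide(FixtureSpec("A" * 10, chain_id="A"))
        m2 = build_ideal_peptide(FixtureSpec("A" * 15, chain_id="B"))
        for res in m2.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([80.0, 0, 0])
        model = StructureModel(m1.residues + m2.residues)
        assert residue_count(model) == 25

    def test_empty(self):
        assert residue_count(StructureModel([])) == 0
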