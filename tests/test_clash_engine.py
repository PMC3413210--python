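import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from clashaudit.clash_engine import (
    UnknownElementError, VdwTable, apply_exclusions, classify_contact,
    detect_clashes, find_contacts, per_100, vdw_radius,
)
from clashaudit.fixtures import FixtureSpec, build_ideal_peptide, contact_scene
from clashaudit.hydrogen_placement import place_riding_hydrogens
from clashaudit.structure_model import AtomRecord
from clashaudit._vec import rotate_points


def h_atom(x, polar=False):
    return AtomRecord(serial=1, name="H", element="H", coords=[x, 0, 0],
                      is_hydrogen=True, polar_aromatic_h=polar)


def o_atom(x):
    return AtomRecord(serial=1, name="O", element="O", coords=[x, 0, 0])


class TestVdwTable:
    def test_primary_h(self):
        assert vdw_radius("H", "primary") == 1.1

    def test_primary_o(self):
        assert vdw_radius("O", "primary") == 1.58

    def test_richardson(self):
        assert vdw_radius("O", "richardson") == 1.40
        assert vdw_radius("H", "richardson", polar_aromatic_h=True) == 1.00
        assert vdw_radius("H", "richardson") == 1.17

    def test_bondi_fallback(self):
        assert vdw_radius("P", "primary") == 1.80

    def test_unknown_element(self):
        with pytest.raises(UnknownElementError):
            vdw_radius("XX")

    def test_override_file(self, tmp_path):
        path = tmp_path / "radii.txt"
        path.write_text("# custom\nH 1.25\n")
        table = VdwTable.from_file(str(path))
        assert table.radius("H") == 1.25
        assert table.radius("C") == 1.77


class TestClassify:
    @pytest.fixture
    def table(self):
        return VdwTable("primary")

    def test_hh_boundary_inclusive(self, table):
        assert classify_contact(h_atom(0), h_atom(1.76), table).clash_class == "clash"
        assert classify_contact(h_atom(0), h_atom(1.761), table).clash_class == "none"

    def test_hh_severe_boundary(self, table):
        assert classify_contact(h_atom(0), h_atom(1.54), table).clash_class == "severe"
        assert classify_contact(h_atom(0), h_atom(1.541), table).clash_class == "clash"

    def test_oo_boundary(self, table):
        assert classify_contact(o_atom(0), o_atom(2.528), table).clash_class == "clash"
        assert classify_contact(o_atom(0), o_atom(2.529), table).clash_class == "none"

    def test_richardson_nonpolar_hh(self):
        table = VdwTable("richardson")
        assert classify_contact(h_atom(0), h_atom(1.94), table).clash_class == "clash"
        assert classify_contact(h_atom(0), h_atom(1.941), table).clash_class == "none"

    def test_richardson_polar_hh(self):
        table = VdwTable("richardson")
        a, b = h_atom(0, polar=True), h_atom(1.60, polar=True)
        assert classify_contact(a, b, table).clash_class == "clash"
        assert classify_contact(a, h_atom(1.601, polar=True), table).clash_class == "none"

    @given(d1=st.floats(0.5, 4.0), d2=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_distance(self, d1, d2):
        table = VdwTable("primary")
        rank = {"severe": 0, "clash": 1, "none": 2}
        c1 = classify_contact(h_atom(0), h_atom(min(d1, d2)), table).clash_class
        c2 = classify_contact(h_atom(0), h_atom(max(d1, d2)), table).clash_class
        assert rank[c1] <= rank[c2]


class TestFindContacts:
    def test_far_pair_empty(self, point_model_factory):
        model = point_model_factory([[0, 0, 0], [10, 0, 0]])
        assert find_contacts(model, 4.0) == []

    def test_pair_reported_once(self, point_model_factory):
        model = point_model_factory([[0, 0, 0], [1, 0, 0]])
        pairs = find_contacts(model, 4.0)
        assert pairs == [(0, 1)]

    def test_matches_brute_force(self, point_model_factory):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 400))
            coords = rng.uniform(0, 20, size=(n, 3))
            model = point_model_factory(coords)
            cutoff = 3.0
            got = set(find_contacts(model, cutoff))
            dm = squareform(pdist(coords))
            want = {(i, j) for i in range(n) for j in range(i + 1, n)
                    if dm[i, j] <= cutoff}
            assert got == want


class TestExclusions:
    def test_backbone_hbond_excluded(self, polyala20_h):
        # helical geometry provides O(i)...H-N(i+4) pairs: none may survive
        report = detect_clashes(polyala20_h)
        assert report.excluded["donor_h"] > 0
        assert report.excluded["donor_acceptor"] > 0
        assert report.n_clashes == 0 and report.n_severe == 0

    def test_geminal_hh_excluded(self, polyala20_h):
        res = polyala20_h.residues[5]
        hb1, hb2 = res.get_atom("HB1"), res.get_atom("HB2")
        kept, tally = apply_exclusions([(hb1.index, hb2.index)], polyala20_h)
        assert kept == []
        assert tally["bonded_path"] == 1

    def test_nonpolar_hh_retained(self, scene50):
        # the engineered methyl H-H pairs have no exclusion rule to hide behind
        report = detect_clashes(scene50)
        assert report.n_clashes + report.n_severe == 2


class TestDetect:
    def test_clean_helix(self, polyala20_h):
        report = detect_clashes(polyala20_h)
        assert report.n_clashes == 0
        assert report.n_severe == 0
        assert report.clashes_per_100 == 0.0

    def test_counts_and_per100(self, scene50):
        report = detect_clashes(scene50)
        assert (report.n_clashes, report.n_severe) == (1, 1)
        assert report.residue_count == 50
        assert report.clashes_per_100 == 2.0
        assert report.severe_per_100 == 2.0

    def test_deterministic(self, scene50):
        r1 = detect_clashes(scene50)
        r2 = detect_clashes(scene50)
        assert r1.n_clashes == r2.n_clashes and r1.n_severe == r2.n_severe
        assert r1.excluded == r2.excluded

    def test_rigid_motion_invariance(self, scene50):
        model = scene50.copy()
        pts = model.coords()
        pts = rotate_points(pts, np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 1.0, 0.5]), 123.0) + np.array([5, -3, 8.0])
        for atom, p in zip(model.atoms(), pts):
            atom.coords = p
        report = detect_clashes(model)
        assert (report.n_clashes, report.n_severe) == (1, 1)

    def test_severe_and_clash_disjoint(self, scene50):
        report = detect_clashes(scene50)
        for f in report.findings:
            assert f.clash_class in ("clash", "severe")
            if f.clash_class == "severe":
                assert f.ratio <= 0.7
            else:
                assert 0.7 < f.ratio <= 0.8

    def test_water_contacts_separate(self, polyala20_h):
        from clashaudit.structure_model import ResidueUnit, build_covalent_graph
        model = polyala20_h.copy()
        res = model.residues[10]
        hb1 = res.get_atom("HB1")
        w = ResidueUnit("W", 1, "", "HOH", is_water=True)
        # water O rammed straight into a methyl H: not a hydrogen bond
        w.atoms.append(AtomRecord(serial=0, name="O", element="O",
                                  coords=hb1.coords + np.array([1.2, 0, 0])))
        model.residues.append(w)
        model.reindex()
        build_covalent_graph(model)
        report = detect_clashes(model)
        assert report.n_clashes == 0 and report.n_severe == 0
        assert len(report.water_findings) >= 1

    def test_symmetry_stub(self, polyala20_h):
        with pytest.raises(NotImplementedError):
            detect_clashes(polyala20_h, include_symmetry=True)


class TestPer100:
    def test_table_totals(self):
        assert per_100(52, 3543) == 1.5
        assert per_100(21, 3543) == 0.6

    def test_zero(self):
        assert per_100(0, 123) == 0.0

    def test_invalid_residue_count(self):
        with pytest.raises(ValueError):
            per_100(1, 0)

    @given(count=st.integers(0, 10_000), residues=st.integers(1, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_definition(self, count, residues):
        assert per_100(count, residues) == pytest.approx(
            round(100.0 * count / residues, 1))
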