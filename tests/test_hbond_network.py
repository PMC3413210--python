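import itertools

import numpy as np
import pytest

from clashaudit.fixtures import (
    FixtureSpec, build_ideal_peptide, build_network_toy, enumerate_optimum,
)
from clashaudit.hbond_network import (
    NetworkCluster, NetworkParams, build_clusters, enumerate_states,
    find_variable_species, optimize_cluster, optimize_network, score_solution,
)
from clashaudit.hydrogen_placement import place_riding_hydrogens
from clashaudit.structure_model import (
    AtomRecord, ResidueUnit, StructureModel, build_covalent_graph,
)


def _all_atom(seq, **kw):
    model = build_ideal_peptide(FixtureSpec(seq, **kw))
    place_riding_hydrogens(model)
    return model


class TestFindSpecies:
    def test_ser_plus_water(self):
        model = _all_atom("ASA")
        res = ResidueUnit("W", 1, "", "HOH", is_water=True)
        og = model.residues[1].get_atom("OG")
        res.atoms.append(AtomRecord(serial=0, name="O", element="O",
                                    coords=og.coords + np.array([3.0, 0, 0])))
        model.residues.append(res)
        model.reindex()
        build_covalent_graph(model)
        place_riding_hydrogens(model)
        species = find_variable_species(model)
        assert len(species) == 2
        assert {s.kind for s in species} == {"hydroxyl", "water"}

    def test_his_six_states(self):
        model = _all_atom("AHA")
        (sp,) = find_variable_species(model)
        assert sp.kind == "his_state"
        assert len(sp.states) == 6
        tags = {s.protonation_tag for s in sp.states}
        assert tags == {"HID", "HIE", "HIP"}

    def test_asn_two_states(self):
        model = _all_atom("ANA")
        (sp,) = find_variable_species(model)
        assert sp.kind == "asn_gln_flip"
        assert [s.label for s in sp.states] == ["asis", "flip"]

    def test_asp_glu_protonation_states(self):
        model = _all_atom("ADA")
        (sp,) = find_variable_species(model)
        assert sp.kind == "asp_glu_state"
        assert len(sp.states) == 5  # deprotonated + 2 oxygens x syn/anti
        assert sum(1 for s in sp.states if s.prior < 0) == 4

    def test_flip_preserves_bond_lengths(self):
        model = _all_atom("ANA")
        (sp,) = find_variable_species(model)
        res = sp.residue
        cg = res.get_atom("CG").coords
        for state in sp.states:
            d1 = np.linalg.norm(state.coords["OD1"] - cg)
            d2 = np.linalg.norm(state.coords["ND2"] - cg)
            assert d1 == pytest.approx(
                np.linalg.norm(res.get_atom("OD1").coords - cg), abs=1e-9)
            assert d2 == pytest.approx(
                np.linalg.norm(res.get_atom("ND2").coords - cg), abs=1e-9)


class TestEnumerateStates:
    def test_aimed_state_closer_than_staggered(self):
        model, _ = build_network_toy("singleton", seed=0)
        (sp,) = find_variable_species(model)
        acceptor = None
        for res in model.residues:
            if res.chain_id == "P":
                acceptor = res.get_atom("O").coords
        aimed = [s for s in sp.states if s.label.startswith("aim")]
        staggered = [s for s in sp.states if s.label.startswith("stag")]
        assert aimed and staggered
        d_aim = min(np.linalg.norm(s.coords["HG"] - acceptor) for s in aimed)
        d_stag = min(np.linalg.norm(s.coords["HG"] - acceptor) for s in staggered)
        assert d_aim < d_stag

    def test_isolated_water_defaults_only(self):
        model = _all_atom("AAA")
        res = ResidueUnit("W", 1, "", "HOH", is_water=True)
        res.atoms.append(AtomRecord(serial=0, name="O", element="O",
                                    coords=[50.0, 50.0, 50.0]))
        model.residues.append(res)
        model.reindex()
        build_covalent_graph(model)
        place_riding_hydrogens(model)
        water = [s for s in find_variable_species(model) if s.kind == "water"][0]
        assert all(s.label.startswith("default") for s in water.states)

    def test_duplicate_torsions_merged(self):
        model = _all_atom("ASA")
        (sp,) = find_variable_species(model)
        # no two states within the merge tolerance of each other
        res = sp.residue
        cb, og = res.get_atom("CB").coords, res.get_atom("OG").coords
        from clashaudit._vec import dihedral
        ca = res.get_atom("CA").coords
        torsions = [dihedral(ca, cb, og, s.coords["HG"]) for s in sp.states]
        for t1, t2 in itertools.combinations(torsions, 2):
            sep = abs((t1 - t2 + 180.0) % 360.0 - 180.0)
            assert sep >= 15.0 - 1e-6


class TestClusters:
    def test_two_distant_sers_singletons(self):
        m1 = _all_atom("ASA", chain_id="A")
        m2 = _all_atom("ASA", chain_id="B")
        for res in m2.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([30.0, 0, 0])
        model = StructureModel(list(m1.residues) + list(m2.residues))
        build_covalent_graph(model)
        species = find_variable_species(model)
        clusters = build_clusters(species, 4.0)
        assert len(clusters) == 2
        assert all(len(c.species) == 1 for c in clusters)

    def test_chain_connectivity(self):
        model, _ = build_network_toy("ser_water_chain", seed=0)
        species = find_variable_species(model)
        clusters = build_clusters(species, 4.0)
        assert len(clusters) == 1
        assert len(clusters[0].species) == 3

    def test_order_invariant(self):
        model, _ = build_network_toy("ser_water_chain", seed=0)
        species = find_variable_species(model)
        c1 = build_clusters(species, 4.0)
        c2 = build_clusters(list(reversed(species)), 4.0)
        assert len(c1) == len(c2)
        assert sorted(len(c.species) for c in c1) == sorted(len(c.species) for c in c2)


class TestScoring:
    def test_empty_cluster_scores_zero(self, polyala20_h):
        sol = score_solution(NetworkCluster([]), (), polyala20_h)
        assert sol.score == 0.0 and sol.n_hbonds == 0

    def test_water_single_acceptor_one_bond(self):
        model, _ = build_network_toy("singleton", seed=0)
        params = NetworkParams()
        species = find_variable_species(model, params)
        cluster = build_clusters(species, 4.0)[0]
        sol = optimize_cluster(cluster, model, seed=0, params=params)
        assert sol.n_hbonds == 1

    def test_h_pointed_at_h_penalized(self):
        # hydroxyl H aimed straight at a methyl H: clash penalty drives the
        # aimed state's score below zero
        model, _ = build_network_toy("singleton", seed=0)
        params = NetworkParams()
        species = find_variable_species(model, params)
        (sp,) = species
        aimed = [i for i, s in enumerate(sp.states) if s.label.startswith("aim")][0]
        h_pos = sp.states[aimed].coords["HG"]
        og = sp.residue.get_atom("OG").coords
        blocker = ResidueUnit("Z", 1, "", "ALA", is_polymer=True)
        h_target = h_pos + 1.6 * (h_pos - og) / np.linalg.norm(h_pos - og)
        blocker.atoms.append(AtomRecord(serial=0, name="HB1", element="H",
                                        coords=h_target, is_hydrogen=True))
        model.residues.append(blocker)
        model.reindex()
        build_covalent_graph(model)
        species = find_variable_species(model, params)
        (sp,) = [s for s in species if s.kind == "hydroxyl"]
        cluster = build_clusters(species, 4.0)
        cluster = [c for c in cluster if sp in c.species][0]
        k = cluster.species.index(sp)
        aimed = [i for i, s in enumerate(sp.states) if s.label.startswith("aim")][0]
        assignment = [0] * len(cluster.species)
        assignment[k] = aimed
        sol = score_solution(cluster, assignment, model, params)
        assert sol.n_clashes + sol.n_severe >= 1
        assert sol.score < 0

    def test_invalid_state_index(self):
        model, _ = build_network_toy("singleton", seed=0)
        species = find_variable_species(model)
        cluster = build_clusters(species, 4.0)[0]
        with pytest.raises(ValueError):
            score_solution(cluster, (99,), model)


class TestOptimize:
    def test_seeded_determinism(self):
        model, _ = build_network_toy("ser_water_chain", seed=0)
        params = NetworkParams()
        species = find_variable_species(model, params)
        cluster = build_clusters(species, 4.0)[0]
        s1 = optimize_cluster(cluster, model, seed=5, params=params,
                              force_stochastic=True)
        s2 = optimize_cluster(cluster, model, seed=5, params=params,
                              force_stochastic=True)
        assert s1.assignment == s2.assignment and s1.score == s2.score

    def test_stochastic_equals_exhaustive(self):
        for kind in ("singleton", "ser_water_chain", "asn_flip", "his_tautomer"):
            model, _ = build_network_toy(kind, seed=0)
            params = NetworkParams()
            species = find_variable_species(model, params)
            for cluster in build_clusters(species, 4.0):
                assert cluster.n_combinations() <= params.exhaustive_limit
                exact = optimize_cluster(cluster, model, seed=0, params=params)
                stoch = optimize_cluster(cluster, model, seed=0, params=params,
                                         force_stochastic=True)
                assert stoch.score == pytest.approx(exact.score, abs=1e-9), kind

    def test_small_clusters_match_brute_force(self):
        model, _ = build_network_toy("mixed", seed=2)
        params = NetworkParams()
        species = find_variable_species(model, params)
        for cluster in build_clusters(species, 4.0):
            if len(cluster.species) > 3:
                continue
            sol = optimize_cluster(cluster, model, seed=1, params=params)
            oracle = enumerate_optimum(cluster, model, params)
            assert sol.score == pytest.approx(oracle.score, abs=1e-9)

    def test_score_at_least_best_greedy_start(self):
        model, _ = build_network_toy("ser_water_chain", seed=0)
        params = NetworkParams()
        species = find_variable_species(model, params)
        cluster = build_clusters(species, 4.0)[0]
        sol = optimize_cluster(cluster, model, seed=3, params=params,
                               force_stochastic=True)
        greedy = score_solution(cluster, (0,) * len(cluster.species), model, params)
        assert sol.score >= greedy.score


class TestOptimizeNetwork:
    def test_no_species_unchanged(self, polyala20_h):
        model = polyala20_h.copy()
        before = model.coords().copy()
        optimize_network(model, seed=0)
        np.testing.assert_allclose(model.coords(), before)
        assert model.network_report["clusters"] == []

    def test_applies_winning_states(self):
        model, optima = build_network_toy("asn_flip", seed=0)
        nd2_before = None
        for res in model.residues:
            if res.res_name == "ASN":
                nd2_before = res.get_atom("ND2").coords.copy()
        optimize_network(model, seed=0)
        for res in model.residues:
            if res.res_name == "ASN":
                assert not np.allclose(res.get_atom("ND2").coords, nd2_before)

    def test_reoptimization_idempotent_in_score(self):
        model, _ = build_network_toy("ser_water_chain", seed=0)
        optimize_network(model, seed=0)
        score1 = sum(c["score"] for c in model.network_report["clusters"])
        optimize_network(model, seed=0)
        score2 = sum(c["score"] for c in model.network_report["clusters"])
        assert score2 == pytest.approx(score1, abs=1e-9)
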