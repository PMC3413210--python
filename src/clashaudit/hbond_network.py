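"""Discrete hydrogen-bond network optimization.

Variable species -- rotatable hydroxyl/sulfhydryl/phenolic hydrogens,
Asp/Glu charge states, His charge/tautomer/flip states, Asn/Gln flips and
water orientations -- are enumerated into discrete states, grouped into
clusters of potentially hydrogen-bonded sites, and each cluster is solved
for the assignment that maximizes hydrogen bonds while avoiding close
nonbonded contacts.  Small clusters are solved exhaustively; larger ones by
multi-start best-response iteration, recombination and simulated annealing.

All weights, cutoffs and schedule parameters are configurable via
:class:`NetworkParams`; the defaults make any clash outweigh any plausible
hydrogen-bond gain.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from clashaudit import data as _data
from clashaudit._vec import angle, dihedral, place_atom, rotate_points, unit
from clashaudit.clash_engine import (
    CLASH_RATIO, SEVERE_RATIO, VdwTable, assign_hbond_roles,
)
from clashaudit.structure_model import (
    AtomRecord, ResidueUnit, StructureModel, build_covalent_graph,
)

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    hbond_da_max: float = 3.5       # donor-acceptor heavy-atom distance
    hbond_ha_max: float = 2.5       # H...acceptor distance
    hbond_angle_min: float = 120.0  # D-H...A angle
    w_hbond: float = 1.0
    w_clash: float = 10.0
    w_severe: float = 100.0
    charge_prior: float = -0.5      # neutral Asp/Glu, charged/neutral-ND1 His
    coupling_cutoff: float = 4.0
    neighbor_search: float = 3.5    # for state enumeration
    torsion_merge_deg: float = 15.0
    n_starts: int = 10
    n_offspring: int = 20
    sa_steps_per_species: int = 200
    sa_t0: float = 1.0
    sa_t1: float = 0.01
    exhaustive_limit: int = 10_000


@dataclass
class State:
    """One discrete configuration of a species: coordinates for every
    variable atom present in this state (hydrogens absent from the mapping do
    not exist in the state)."""
    label: str
    coords: dict[str, np.ndarray]
    protonation_tag: str | None = None
    prior: float = 0.0


@dataclass
class VariableSpecies:
    kind: str                      # hydroxyl|sulfhydryl|phenolic|asp_glu_state|his_state|asn_gln_flip|water
    residue: ResidueUnit
    res_index: int
    polar_atom_names: list[str]
    states: list[State] = field(default_factory=list)
    current_state_index: int = 0
    # name -> (anchor atom index in model, is_hydrogen, parent heavy name)
    anchors: dict[str, tuple[int | None, bool, str | None]] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.residue.label}:{self.kind}"


@dataclass
class NetworkCluster:
    species: list[VariableSpecies]
    edges: list[tuple[int, int]] = field(default_factory=list)

    def n_combinations(self) -> int:
        n = 1
        for s in self.species:
            n *= max(len(s.states), 1)
        return n


@dataclass
class NetworkSolution:
    assignment: tuple[int, ...]
    score: float
    n_hbonds: int
    n_clashes: int
    n_severe: int = 0


# ---------------------------------------------------------------------------
# species discovery and state enumeration
# ---------------------------------------------------------------------------

ROTATABLE_KINDS = {"SER": ("OG", "hydroxyl"), "THR": ("OG1", "hydroxyl"),
                   "TYR": ("OH", "phenolic"), "CYS": ("SG", "sulfhydryl")}


def _polar_partners(model: StructureModel, center: np.ndarray, radius: float,
                    exclude_res: int) -> tuple[list[int], list[int]]:
    """(acceptor, donor) atom indices near a point, excluding one residue."""
    roles = assign_hbond_roles(model)
    acc, don = [], []
    for idx in roles.acceptors:
        if model.residue_index_of(idx) == exclude_res:
            continue
        if np.linalg.norm(model.atoms()[idx].coords - center) <= radius:
            acc.append(idx)
    for idx in roles.donors:
        if model.residue_index_of(idx) == exclude_res:
            continue
        if np.linalg.norm(model.atoms()[idx].coords - center) <= radius:
            don.append(idx)
    return acc, don


def _torsion_of(model, g, b, p, target: np.ndarray) -> float:
    return dihedral(g.coords, b.coords, p.coords, target)


def _merge_torsions(candidates: list[tuple[str, float]], tol: float) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    for label, t in candidates:
        t = (t + 180.0) % 360.0 - 180.0
        if not any(abs(((t - u) + 180.0) % 360.0 - 180.0) < tol for _, u in out):
            out.append((label, t))
    return out


def enumerate_states(species: VariableSpecies, model: StructureModel,
                     params: NetworkParams | None = None) -> list[State]:
    """Plausible discrete states for one species (see module docstring)."""
    params = params or NetworkParams()
    kind = species.kind
    res = species.residue
    geo = _data.h_geometry()

    if kind in ("hydroxyl", "sulfhydryl", "phenolic"):
        return _hydroxyl_states(species, model, params)
    if kind == "asp_glu_state":
        return _asp_glu_states(species, model, params)
    if kind == "asn_gln_flip":
        return _flip_states(species, model)
    if kind == "his_state":
        return _his_states(species, model)
    if kind == "water":
        return _water_states(species, model, params)
    raise ValueError(f"unknown species kind {kind!r}")


def _hydroxyl_states(species, model, params) -> list[State]:
    res = species.residue
    pname = species.polar_atom_names[0]
    p = res.get_atom(pname)
    hname = _data.residue_templates()[res.template_name()]["hydrogens"][pname][0]
    heavies = [model.atoms()[j] for j in sorted(model.bonded(p.index))
               if not model.atoms()[j].is_hydrogen]
    b = heavies[0]
    g = next(model.atoms()[j] for j in sorted(model.bonded(b.index))
             if j != p.index and not model.atoms()[j].is_hydrogen)
    geo = _data.h_geometry()
    length = geo["bond_lengths"]["S" if p.element == "S" else "O"]
    theta = geo["angles"]["sulfhydryl" if species.kind == "sulfhydryl" else "hydroxyl"]

    candidates = [("stag+60", 60.0), ("stag180", 180.0), ("stag-60", -60.0)]
    acc, don = _polar_partners(model, p.coords, params.neighbor_search, species.res_index)
    for idx in acc:
        t = _torsion_of(model, g, b, p, model.atoms()[idx].coords)
        candidates.insert(0, (f"aim_a{idx}", t))
    for idx in don:
        t = _torsion_of(model, g, b, p, model.atoms()[idx].coords)
        candidates.append((f"anti_d{idx}", t + 180.0))
    merged = _merge_torsions(candidates, params.torsion_merge_deg)
    return [State(label, {hname: place_atom(g.coords, b.coords, p.coords, length, theta, t)})
            for label, t in merged]


def _asp_glu_states(species, model, params) -> list[State]:
    res = species.residue
    if res.template_name() == "ASP":
        cb, cx, o1, o2 = "CB", "CG", "OD1", "OD2"
        hnames = {"OD1": "HD1", "OD2": "HD2"}
    else:
        cb, cx, o1, o2 = "CG", "CD", "OE1", "OE2"
        hnames = {"OE1": "HE1", "OE2": "HE2"}
    a_cb, a_cx = res.get_atom(cb), res.get_atom(cx)
    states = [State("deprotonated", {}, protonation_tag="charged")]
    for oname in (o1, o2):
        o = res.get_atom(oname)
        if o is None:
            continue
        for torsion, tag in ((0.0, "syn"), (180.0, "anti")):
            h = place_atom(a_cb.coords, a_cx.coords, o.coords, 0.96, 113.0, torsion)
            states.append(State(f"prot_{oname}_{tag}", {hnames[oname]: h},
                                protonation_tag="neutral", prior=-0.5))
    return states


def _flip_states(species, model) -> list[State]:
    res = species.residue
    tpl = _data.residue_templates()[res.template_name()]
    flip = tpl["flip"]
    axis_a = res.get_atom(flip["axis"][0])
    axis_b = res.get_atom(flip["axis"][1])
    names = [n for n in flip["atoms"] if res.get_atom(n) is not None]
    pts = np.array([res.get_atom(n).coords for n in names])
    flipped = rotate_points(pts, axis_a.coords, axis_b.coords - axis_a.coords, 180.0)
    identity = State("asis", {n: res.get_atom(n).coords.copy() for n in names})
    return [identity, State("flip", {n: flipped[i] for i, n in enumerate(names)})]


def _his_states(species, model) -> list[State]:
    """3 protonation/tautomer states x 2 flip orientations."""
    res = species.residue
    ring = ["ND1", "CD2", "CE1", "NE2"]
    axis_a, axis_b = res.get_atom("CB"), res.get_atom("CG")
    cg = res.get_atom("CG")
    base = {n: res.get_atom(n).coords.copy() for n in ring if res.get_atom(n) is not None}
    geo = _data.h_geometry()

    def ring_h(coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Ring C-H and N-H positions from ring geometry (anti-bisector)."""
        out = {}
        frames = {"HD2": ("CD2", "CG", "NE2"), "HE1": ("CE1", "ND1", "NE2"),
                  "HD1": ("ND1", "CG", "CE1"), "HE2": ("NE2", "CD2", "CE1")}
        pos = dict(coords)
        pos["CG"] = cg.coords
        for hname, (center, n1, n2) in frames.items():
            c, u1, u2 = pos[center], pos[n1], pos[n2]
            direction = unit(-(unit(u1 - c) + unit(u2 - c)))
            length = geo["bond_lengths"]["N" if center.startswith("N") else "C"]
            out[hname] = c + length * direction
        return out

    states = []
    for flip_label, coords in (("", base), ("_flip", None)):
        if coords is None:
            pts = np.array([base[n] for n in ring])
            rot = rotate_points(pts, axis_a.coords, axis_b.coords - axis_a.coords, 180.0)
            coords = {n: rot[i] for i, n in enumerate(ring)}
        h = ring_h(coords)
        for tag, hs, prior in (("HIE", ["HD2", "HE1", "HE2"], 0.0),
                               ("HID", ["HD2", "HE1", "HD1"], -0.5),
                               ("HIP", ["HD2", "HE1", "HD1", "HE2"], -0.5)):
            st = dict(coords)
            st.update({k: h[k] for k in hs})
            states.append(State(tag + flip_label, st, protonation_tag=tag, prior=prior))
    return states


def _water_states(species, model, params) -> list[State]:
    res = species.residue
    o = res.get_atom("O")
    geo = _data.h_geometry()
    ang = geo["angles"]["water"]
    length = geo["bond_lengths"]["O"]
    acc, don = _polar_partners(model, o.coords, params.neighbor_search, species.res_index)
    acc = sorted(acc, key=lambda i: np.linalg.norm(model.atoms()[i].coords - o.coords))[:4]
    don = sorted(don, key=lambda i: np.linalg.norm(model.atoms()[i].coords - o.coords))[:4]

    def pair_state(u1: np.ndarray, u2: np.ndarray) -> dict[str, np.ndarray]:
        """H1 along u1; H2 in the (u1,u2) plane at the water angle."""
        u1 = unit(u1)
        v = u2 - np.dot(u2, u1) * u1
        if np.linalg.norm(v) < 1e-8:
            v = _any_perpendicular(u1)
        v = unit(v)
        t = np.radians(ang)
        h2dir = np.cos(t) * u1 + np.sin(t) * v
        return {"H1": o.coords + length * u1, "H2": o.coords + length * h2dir}

    states: list[tuple[str, dict]] = []
    for i, j in itertools.combinations(range(len(acc)), 2):
        ai = model.atoms()[acc[i]].coords - o.coords
        aj = model.atoms()[acc[j]].coords - o.coords
        states.append((f"pair_{acc[i]}_{acc[j]}", pair_state(ai, aj)))
    for i in acc:
        u = model.atoms()[i].coords - o.coords
        states.append((f"aim_{i}", pair_state(u, _any_perpendicular(unit(u)))))
    for i in don:
        # both hydrogens away from the donor: lone pair faces it
        u = unit(o.coords - model.atoms()[i].coords)
        states.append((f"anti_{i}", pair_state(
            _rotated(u, _any_perpendicular(u), ang / 2.0),
            _rotated(u, -_any_perpendicular(u), ang / 2.0))))
    states.append(("default_x", pair_state(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))))
    states.append(("default_z", pair_state(np.array([0, 0, 1.0]), np.array([1.0, 0, 0]))))

    out: list[State] = []
    for label, coords in states:
        dup = any(np.linalg.norm(coords["H1"] - s.coords["H1"]) < 0.25
                  and np.linalg.norm(coords["H2"] - s.coords["H2"]) < 0.25
                  for s in out)
        if not dup:
            out.append(State(label, coords))
    return out


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0, 1.0, 0])
    return unit(np.cross(u, ref))


def _rotated(u: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    return rotate_points(u[None, :], np.zeros(3), axis, deg)[0]


def find_variable_species(model: StructureModel,
                          params: NetworkParams | None = None) -> list[VariableSpecies]:
    """One species per rotatable polar hydrogen, Asp/Glu, His, Asn/Gln and
    water; states enumerated immediately.  Requires an all-atom model with a
    covalent graph."""
    params = params or NetworkParams()
    templates = _data.residue_templates()
    species: list[VariableSpecies] = []
    for ri, res in enumerate(model.residues):
        tname = res.template_name()
        if tname is None:
            continue
        sp = None
        if tname in ROTATABLE_KINDS:
            pname, kind = ROTATABLE_KINDS[tname]
            if res.get_atom(pname) is not None:
                sp = VariableSpecies(kind, res, ri, [pname])
        elif tname in ("ASP", "GLU"):
            o1, o2 = ("OD1", "OD2") if tname == "ASP" else ("OE1", "OE2")
            if res.get_atom(o1) is not None and res.get_atom(o2) is not None:
                sp = VariableSpecies("asp_glu_state", res, ri, [o1, o2])
        elif tname == "HIS":
            if all(res.get_atom(n) is not None for n in ("CB", "CG", "ND1", "NE2", "CD2", "CE1")):
                sp = VariableSpecies("his_state", res, ri, ["ND1", "NE2"])
        elif tname in ("ASN", "GLN"):
            flip = templates[tname]["flip"]
            if all(res.get_atom(n) is not None for n in flip["axis"]):
                sp = VariableSpecies("asn_gln_flip", res, ri,
                                     [flip["swap"][0][0], flip["swap"][0][1]])
        elif tname == "HOH":
            if res.get_atom("O") is not None:
                sp = VariableSpecies("water", res, ri, ["O"])
        if sp is None:
            continue
        try:
            sp.states = enumerate_states(sp, model, params)
        except (StopIteration, AttributeError, KeyError):
            logger.warning("could not enumerate states for %s; skipped", sp.label)
            continue
        if not sp.states:
            continue
        _assign_anchors(sp, model)
        species.append(sp)
    return species


def _assign_anchors(sp: VariableSpecies, model: StructureModel) -> None:
    """Map every variable atom name to a model atom index usable for
    bonded-path exclusions (hydrogens anchor at their parent when absent)."""
    res = sp.residue
    tpl = _data.residue_templates()[res.template_name()]
    h_parent = {h: p for p, hs in tpl["hydrogens"].items() for h in hs}
    # Asp/Glu carboxyl hydrogens are not in the default template
    if sp.kind == "asp_glu_state":
        if res.template_name() == "ASP":
            h_parent.update({"HD1": "OD1", "HD2": "OD2"})
        else:
            h_parent.update({"HE1": "OE1", "HE2": "OE2"})
    names = {n for st in sp.states for n in st.coords}
    for name in names:
        atom = res.get_atom(name)
        if atom is not None and not atom.is_hydrogen:
            sp.anchors[name] = (atom.index, False, None)
        else:
            parent = h_parent.get(name)
            p_atom = res.get_atom(parent) if parent else None
            sp.anchors[name] = (p_atom.index if p_atom else None, True, parent)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def build_clusters(species: list[VariableSpecies],
                   coupling_cutoff: float = 4.0) -> list[NetworkCluster]:
    """Connected components of the graph linking species whose polar atoms
    lie within ``coupling_cutoff``."""
    n = len(species)
    centers = []
    for sp in species:
        pts = [sp.residue.get_atom(nm).coords for nm in sp.polar_atom_names
               if sp.residue.get_atom(nm) is not None]
        centers.append(np.array(pts))
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            dmin = min(float(np.linalg.norm(a - b))
                       for a in centers[i] for b in centers[j])
            if dmin <= coupling_cutoff:
                edges.append((i, j))
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for members in groups.values():
        mset = set(members)
        local = {g: k for k, g in enumerate(members)}
        cluster_edges = [(local[i], local[j]) for i, j in edges
                         if i in mset and j in mset]
        clusters.append(NetworkCluster([species[i] for i in members], cluster_edges))
    clusters.sort(key=lambda c: (c.species[0].res_index, c.species[0].kind))
    return clusters


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class _ClusterContext:
    """Precomputed static environment for scoring one cluster."""

    INTERACT_RADIUS = 4.5

    def __init__(self, cluster: NetworkCluster, model: StructureModel,
                 params: NetworkParams):
        self.cluster = cluster
        self.model = model
        self.params = params
        self.table = VdwTable("primary")
        atoms = model.atoms()
        var = set()
        for sp in cluster.species:
            for name in sp.anchors:
                atom = sp.residue.get_atom(name)
                if atom is not None:
                    var.add(atom.index)
        self.var_indices = var
        self.static_indices = np.array(
            [i for i in range(model.n_atoms()) if i not in var], dtype=int)
        coords = model.coords()
        self.static_tree = (cKDTree(coords[self.static_indices])
                            if len(self.static_indices) else None)
        roles = assign_hbond_roles(model)
        self.static_donors = roles.donors - var
        self.static_acceptors = roles.acceptors - var
        self.static_donor_h = [
            (i, next(iter(model.bonded(i) & roles.donors), None))
            for i in roles.donor_hydrogens if i not in var]
        self.static_donor_h = [(h, p) for h, p in self.static_donor_h if p is not None]

    def static_near(self, point: np.ndarray) -> list[int]:
        if self.static_tree is None:
            return []
        idx = self.static_tree.query_ball_point(point, self.INTERACT_RADIUS)
        return [int(self.static_indices[k]) for k in idx]


def _species_roles(sp: VariableSpecies, state: State) -> tuple[set[str], set[str], dict[str, str]]:
    """(donor heavy names, acceptor heavy names, donor H name -> parent name)
    for one state, in species-local atom names."""
    res = sp.residue
    tpl = _data.residue_templates()[res.template_name()]
    h_parent = {h: p for p, hs in tpl["hydrogens"].items() for h in hs}
    if sp.kind == "asp_glu_state":
        h_parent.update({"HD1": "OD1", "HD2": "OD2", "HE1": "OE1", "HE2": "OE2"})
    donors, acceptors, dh = set(), set(), {}
    present_h = {n for n in state.coords if n.startswith("H") or n[:1] == "D"}
    for h in present_h:
        p = h_parent.get(h)
        if p:
            donors.add(p)
            dh[h] = p
    if sp.kind in ("hydroxyl", "phenolic"):
        acceptors.add(sp.polar_atom_names[0])
    elif sp.kind == "sulfhydryl":
        acceptors.add("SG")
    elif sp.kind == "asp_glu_state":
        acceptors.update(sp.polar_atom_names)
    elif sp.kind == "his_state":
        for n in ("ND1", "NE2"):
            if n not in donors:
                acceptors.add(n)
    elif sp.kind == "asn_gln_flip":
        acceptors.add(sp.polar_atom_names[0])  # OD1 / OE1
    elif sp.kind == "water":
        acceptors.add("O")
    return donors, acceptors, dh


def _atom_position(sp: VariableSpecies, state: State, name: str) -> np.ndarray:
    if name in state.coords:
        return state.coords[name]
    return sp.residue.get_atom(name).coords


def score_solution(cluster: NetworkCluster, assignment,
                   model: StructureModel, params: NetworkParams | None = None,
                   context: _ClusterContext | None = None) -> NetworkSolution:
    """Score one assignment of states to the cluster's species.

    score = w_hbond * n_hbonds - w_clash * n_clashes - w_severe * n_severe
            + sum of state priors.
    """
    params = params or NetworkParams()
    ctx = context or _ClusterContext(cluster, model, params)
    assignment = tuple(assignment)
    if len(assignment) != len(cluster.species):
        raise ValueError("assignment length does not match cluster size")
    for sp, si in zip(cluster.species, assignment):
        if not 0 <= si < len(sp.states):
            raise ValueError(f"invalid state index {si} for {sp.label}")

    atoms = model.atoms()
    n_hbonds = 0
    n_clash = 0
    n_severe = 0
    prior = 0.0

    per_species = []
    for sp, si in zip(cluster.species, assignment):
        state = sp.states[si]
        donors, acceptors, dh = _species_roles(sp, state)
        per_species.append((sp, state, donors, acceptors, dh))
        prior += state.prior

    # ---- hydrogen bonds: variable donor H -> all acceptors --------------
    def hbond_ok(d_pos, h_pos, a_pos) -> bool:
        if np.linalg.norm(h_pos - a_pos) > params.hbond_ha_max:
            return False
        if np.linalg.norm(d_pos - a_pos) > params.hbond_da_max:
            return False
        return angle(d_pos, h_pos, a_pos) >= params.hbond_angle_min

    for k, (sp, state, donors, acceptors, dh) in enumerate(per_species):
        for hname, pname in dh.items():
            h_pos = state.coords[hname]
            d_pos = _atom_position(sp, state, pname)
            found = False
            for aidx in ctx.static_near(h_pos):
                if aidx in ctx.static_acceptors and \
                        hbond_ok(d_pos, h_pos, atoms[aidx].coords):
                    found = True
                    break
            if not found:
                for k2, (sp2, state2, _, acceptors2, _) in enumerate(per_species):
                    if k2 == k:
                        continue
                    for aname in acceptors2:
                        a_pos = _atom_position(sp2, state2, aname)
                        if hbond_ok(d_pos, h_pos, a_pos):
                            found = True
                            break
                    if found:
                        break
            if found:
                n_hbonds += 1

    # ---- hydrogen bonds: static donor H -> variable acceptors -----------
    for hidx, pidx in ctx.static_donor_h:
        h_pos = atoms[hidx].coords
        d_pos = atoms[pidx].coords
        for sp2, state2, _, acceptors2, _ in per_species:
            done = False
            for aname in acceptors2:
                if hbond_ok(d_pos, h_pos, _atom_position(sp2, state2, aname)):
                    n_hbonds += 1
                    done = True
                    break
            if done:
                break

    # ---- clashes --------------------------------------------------------
    def pair_class(elem_a, polar_a, pos_a, elem_b, polar_b, pos_b) -> str:
        d = float(np.linalg.norm(pos_a - pos_b))
        rsum = ctx.table.radius(elem_a, polar_a) + ctx.table.radius(elem_b, polar_b)
        r = d / rsum
        if r <= SEVERE_RATIO:
            return "severe"
        if r <= CLASH_RATIO:
            return "clash"
        return "none"

    templates = _data.residue_templates()
    for k, (sp, state, donors, acceptors, dh) in enumerate(per_species):
        res = sp.residue
        tpl = templates[res.template_name()]
        flip = tpl["flip"]
        for name, pos in state.coords.items():
            anchor, is_h, parent = sp.anchors.get(name, (None, True, None))
            if anchor is None:
                continue
            elem = "H" if is_h else res.get_atom(name).element
            polar = is_h  # variable hydrogens sit on N/O/S or aromatic ring
            a_donor_heavy = (not is_h) and name in donors
            a_acceptor = (not is_h) and name in acceptors
            a_donor_h = is_h and name in dh

            # vs static environment
            for sidx in ctx.static_near(pos):
                satom = atoms[sidx]
                depth = 2 if is_h else 3  # anchor path + 1 bond for the H itself
                if ctx.model.bond_path_within(anchor, sidx, depth):
                    continue
                if a_donor_heavy and sidx in ctx.static_acceptors:
                    continue
                if a_acceptor and sidx in ctx.static_donors:
                    continue
                if a_donor_h and sidx in ctx.static_acceptors:
                    continue
                if a_acceptor and any(h == sidx for h, _ in ctx.static_donor_h):
                    continue
                if flip and name in flip["atoms"] and \
                        ctx.model.residue_index_of(sidx) == sp.res_index and \
                        satom.name in flip["atoms"]:
                    continue
                cls = pair_class(elem, polar, pos, satom.element,
                                 satom.polar_aromatic_h, satom.coords)
                if cls == "severe":
                    n_severe += 1
                elif cls == "clash":
                    n_clash += 1

            # vs other species (count each unordered pair once)
            for k2 in range(k + 1, len(per_species)):
                sp2, state2, donors2, acceptors2, dh2 = per_species[k2]
                for name2, pos2 in state2.coords.items():
                    anchor2, is_h2, _ = sp2.anchors.get(name2, (None, True, None))
                    if anchor2 is None:
                        continue
                    if a_donor_heavy and (name2 in acceptors2) and not is_h2:
                        continue
                    if a_acceptor and not is_h2 and name2 in donors2:
                        continue
                    if a_donor_h and not is_h2 and name2 in acceptors2:
                        continue
                    if a_acceptor and is_h2 and name2 in dh2:
                        continue
                    elem2 = "H" if is_h2 else sp2.residue.get_atom(name2).element
                    cls = pair_class(elem, polar, pos, elem2, is_h2, pos2)
                    if cls == "severe":
                        n_severe += 1
                    elif cls == "clash":
                        n_clash += 1

    score = (params.w_hbond * n_hbonds - params.w_clash * n_clash
             - params.w_severe * n_severe + prior)
    return NetworkSolution(assignment, score, n_hbonds, n_clash, n_severe)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def _best_response(cluster, model, params, ctx, assignment, cache) -> tuple[tuple, float]:
    assignment = list(assignment)
    changed = True
    sweeps = 0
    while changed and sweeps < 50:
        changed = False
        sweeps += 1
        for k, sp in enumerate(cluster.species):
            best_si, best_score = assignment[k], None
            for si in range(len(sp.states)):
                assignment[k] = si
                key = tuple(assignment)
                if key not in cache:
                    cache[key] = score_solution(cluster, key, model, params, ctx).score
                sc = cache[key]
                if best_score is None or sc > best_score:
                    best_si, best_score = si, sc
            if assignment[k] != best_si:
                changed = True
            assignment[k] = best_si
    key = tuple(assignment)
    return key, cache[key]


def optimize_cluster(cluster: NetworkCluster, model: StructureModel,
                     seed: int = 0, params: NetworkParams | None = None,
                     force_stochastic: bool = False) -> NetworkSolution:
    """Best state assignment for one cluster.

    Exhaustive enumeration when the state space has at most
    ``params.exhaustive_limit`` combinations (unless ``force_stochastic``);
    otherwise multi-start best-response, recombination of top solutions and
    simulated-annealing refinement.  Deterministic for a fixed seed.
    """
    params = params or NetworkParams()
    ctx = _ClusterContext(cluster, model, params)
    sizes = [len(sp.states) for sp in cluster.species]
    if not sizes:
        return NetworkSolution((), 0.0, 0, 0, 0)

    if cluster.n_combinations() <= params.exhaustive_limit and not force_stochastic:
        best = None
        for assignment in itertools.product(*(range(s) for s in sizes)):
            sol = score_solution(cluster, assignment, model, params, ctx)
            if best is None or sol.score > best.score:
                best = sol
        return best

    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}
    solutions: list[tuple[tuple, float]] = []
    for _ in range(params.n_starts):
        start = tuple(int(rng.integers(s)) for s in sizes)
        solutions.append(_best_response(cluster, model, params, ctx, start, cache))
    solutions.sort(key=lambda t: -t[1])
    best_assignment, best_score = solutions[0]

    # recombination of top solutions
    top = [a for a, _ in solutions[:5]]
    for _ in range(params.n_offspring):
        p1, p2 = top[int(rng.integers(len(top)))], top[int(rng.integers(len(top)))]
        child = tuple(p1[k] if rng.random() < 0.5 else p2[k] for k in range(len(sizes)))
        child, sc = _best_response(cluster, model, params, ctx, child, cache)
        if sc > best_score:
            best_assignment, best_score = child, sc

    # simulated annealing from the incumbent
    steps = params.sa_steps_per_species * len(sizes)
    current = list(best_assignment)
    current_score = best_score
    for step in range(steps):
        t = params.sa_t0 * (params.sa_t1 / params.sa_t0) ** (step / max(steps - 1, 1))
        k = int(rng.integers(len(sizes)))
        if sizes[k] < 2:
            continue
        old = current[k]
        new = int(rng.integers(sizes[k] - 1))
        if new >= old:
            new += 1
        current[k] = new
        key = tuple(current)
        if key not in cache:
            cache[key] = score_solution(cluster, key, model, params, ctx).score
        delta = cache[key] - current_score
        if delta >= 0 or rng.random() < math.exp(delta / t):
            current_score = cache[key]
            if current_score > best_score:
                best_assignment, best_score = key, current_score
        else:
            current[k] = old
    return score_solution(cluster, best_assignment, model, params, ctx)


def apply_solution(cluster: NetworkCluster, solution: NetworkSolution,
                   model: StructureModel) -> None:
    """Write the winning states into the model (coordinates set, hydrogens
    added/removed, protonation tags recorded); rebuilds the covalent graph."""
    for sp, si in zip(cluster.species, solution.assignment):
        state = sp.states[si]
        sp.current_state_index = si
        res = sp.residue
        present = set(state.coords)
        variable = set(sp.anchors)
        for name in sorted(variable):
            atom = res.get_atom(name)
            if name in present:
                if atom is not None:
                    atom.coords = np.asarray(state.coords[name], dtype=float)
                else:
                    _, is_h, parent = sp.anchors[name]
                    p_atom = res.get_atom(parent) if parent else None
                    res.atoms.append(AtomRecord(
                        serial=0, name=name, element="H" if is_h else name[0],
                        coords=state.coords[name],
                        occupancy=p_atom.occupancy if p_atom else 1.0,
                        b_factor=p_atom.b_factor if p_atom else 0.0,
                        altloc=p_atom.altloc if p_atom else "",
                        is_hydrogen=is_h))
            elif atom is not None and atom.is_hydrogen:
                res.atoms.remove(atom)
    model.reindex()
    build_covalent_graph(model)


def optimize_network(model: StructureModel, seed: int = 0,
                     params: NetworkParams | None = None) -> StructureModel:
    """Optimize every cluster independently and apply the winning states.

    The per-cluster report is attached as ``model.network_report``.
    Requires an all-atom model with a covalent graph; returns the model.
    """
    params = params or NetworkParams()
    species = find_variable_species(model, params)
    clusters = build_clusters(species, params.coupling_cutoff)
    report = []
    for ci, cluster in enumerate(clusters):
        # earlier clusters may have added/removed hydrogens: refresh indices
        for sp in cluster.species:
            _assign_anchors(sp, model)
        sol = optimize_cluster(cluster, model, seed=seed + ci, params=params)
        apply_solution(cluster, sol, model)
        report.append({
            "cluster": ci,
            "species": [sp.label for sp in cluster.species],
            "n_states": [len(sp.states) for sp in cluster.species],
            "chosen": [sp.states[si].label
                       for sp, si in zip(cluster.species, sol.assignment)],
            "score": sol.score,
            "n_hbonds": sol.n_hbonds,
            "n_clashes": sol.n_clashes,
            "n_severe": sol.n_severe,
        })
    model.network_report = {"seed": seed, "params": asdict(params), "clusters": report}
    return model
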