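"""Synthetic structure generator with known ground truth.

Peptides are built from internal coordinates using the *same* geometry-target
table the validators read, so bond/angle deviations are exactly zero by
construction for acyclic residues (ring closures are least-squares fitted
and carry deviations at numerical noise level relative to the slightly
over-determined ring targets).  Contacts are engineered by rigid-body
translation of whole chains, and geometry noise is injected in internal
coordinates so RMS Z recovery is exact in expectation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from clashaudit import data as _data
from clashaudit._vec import branch_dihedral, dihedral, place_atom, rotate_points, unit
from clashaudit.clash_engine import VdwTable, detect_clashes
from clashaudit.geometry_stats import GeometryTargets
from clashaudit.hbond_network import (
    NetworkCluster, NetworkParams, NetworkSolution, build_clusters,
    find_variable_species, score_solution,
)
from clashaudit.hydrogen_placement import place_riding_hydrogens
from clashaudit.structure_model import (
    AtomRecord, ResidueUnit, StructureModel, build_covalent_graph,
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

RING_ATOMS = {
    "PHE": ["CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "HIS": ["ND1", "CD2", "CE1", "NE2"],
    "TRP": ["CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}


#: Approximate planar ring coordinates with CB at the origin and CG at
#: (1.50, 0); used only as least-squares starting points.
_CANONICAL_RING_2D = {
    "PHE": {"CD1": (2.20, 1.20), "CD2": (2.20, -1.20), "CE1": (3.59, 1.20),
            "CE2": (3.59, -1.20), "CZ": (4.28, 0.0)},
    "TYR": {"CD1": (2.20, 1.20), "CD2": (2.20, -1.20), "CE1": (3.59, 1.20),
            "CE2": (3.59, -1.20), "CZ": (4.28, 0.0), "OH": (5.66, 0.0)},
    "HIS": {"ND1": (2.29, 1.09), "CE1": (3.58, 0.67), "NE2": (3.58, -0.67),
            "CD2": (2.29, -1.09)},
    "TRP": {"CD1": (2.29, 1.09), "NE1": (3.58, 0.67), "CE2": (3.58, -0.67),
            "CD2": (2.29, -1.09), "CZ2": (4.63, -1.55), "CH2": (4.35, -2.91),
            "CZ3": (3.03, -3.37), "CE3": (1.99, -2.47)},
}


@dataclass
class FixtureSpec:
    sequence: str
    phi: float | list[float] = -57.0
    psi: float | list[float] = -47.0
    omega: float | list[float] = 180.0
    chi: float = 180.0
    chain_id: str = "A"
    start_seq: int = 1
    seed: int = 0
    bond_noise_k: float = 0.0
    angle_noise_k: float = 0.0

    def per_residue(self, value, i: int) -> float:
        return value[i] if isinstance(value, (list, tuple)) else value


class _NoisyTargets:
    """Target lookup that adds k*sigma*z Gaussian noise per query, drawn in
    deterministic construction order from a seeded generator."""

    def __init__(self, spec: FixtureSpec, targets: GeometryTargets):
        self.spec = spec
        self.targets = targets
        self.rng = np.random.default_rng(spec.seed)

    def bond(self, res: str, a1: str, a2: str) -> float:
        tgt = self.targets.bond(res, a1, a2)
        if tgt is None:
            raise KeyError(f"no bond target for {res} {a1}-{a2}")
        z = self.rng.standard_normal()
        return tgt[0] + self.spec.bond_noise_k * tgt[1] * z

    def angle(self, res: str, a1: str, a2: str, a3: str) -> float:
        tgt = self.targets.angle(res, a1, a2, a3)
        if tgt is None:
            raise KeyError(f"no angle target for {res} {a1}-{a2}-{a3}")
        z = self.rng.standard_normal()
        return tgt[0] + self.spec.angle_noise_k * tgt[1] * z


# ---------------------------------------------------------------------------
# ideal peptide construction
# ---------------------------------------------------------------------------

def build_ideal_peptide(spec: FixtureSpec,
                        targets: GeometryTargets | None = None) -> StructureModel:
    """Build a peptide with every (acyclic) bond and angle exactly on target.

    Heavy atoms only; call :func:`clashaudit.hydrogen_placement.
    place_riding_hydrogens` afterwards for an all-atom model.  Deterministic
    for a fixed spec.
    """
    for letter in spec.sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
    targets = targets or GeometryTargets()
    T = _NoisyTargets(spec, targets)
    seq3 = [ONE_TO_THREE[c] for c in spec.sequence]
    n = len(seq3)

    residues = [ResidueUnit(spec.chain_id, spec.start_seq + i, "", seq3[i],
                            is_polymer=True) for i in range(n)]
    pos: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]

    # backbone
    for i, res in enumerate(seq3):
        if i == 0:
            n_ca = T.bond(res, "N", "CA")
            ca_c = T.bond(res, "CA", "C")
            theta = T.angle(res, "N", "CA", "C")
            pos[0]["N"] = np.zeros(3)
            pos[0]["CA"] = np.array([n_ca, 0.0, 0.0])
            t = np.radians(180.0 - theta)
            pos[0]["C"] = pos[0]["CA"] + ca_c * np.array([np.cos(t), np.sin(t), 0.0])
        else:
            prev = seq3[i - 1]
            psi = spec.per_residue(spec.psi, i - 1)
            omega = spec.per_residue(spec.omega, i - 1)
            phi = spec.per_residue(spec.phi, i)
            pos[i]["N"] = place_atom(pos[i - 1]["N"], pos[i - 1]["CA"], pos[i - 1]["C"],
                                     T.bond(prev, "C", "+N"),
                                     T.angle(prev, "CA", "C", "+N"), psi)
            pos[i]["CA"] = place_atom(pos[i - 1]["CA"], pos[i - 1]["C"], pos[i]["N"],
                                      T.bond(res, "N", "CA"),
                                      T.angle(res, "-C", "N", "CA"), omega)
            pos[i]["C"] = place_atom(pos[i - 1]["C"], pos[i]["N"], pos[i]["CA"],
                                     T.bond(res, "CA", "C"),
                                     T.angle(res, "N", "CA", "C"), phi)
    # carbonyl O: anti to the next N about the CA-C axis, i.e. psi + 180
    for i, res in enumerate(seq3):
        psi = spec.per_residue(spec.psi, i)
        pos[i]["O"] = place_atom(pos[i]["N"], pos[i]["CA"], pos[i]["C"],
                                 T.bond(res, "C", "O"),
                                 T.angle(res, "CA", "C", "O"), psi + 180.0)

    # side chains
    for i, res in enumerate(seq3):
        if res == "GLY":
            continue
        prev_c = pos[i - 1]["C"] if i > 0 else None
        _build_side_chain(T, res, pos[i], spec.chi, prev_c)

    # assemble (PDB-ish atom order: N, CA, C, O, then side chain)
    templates = _data.residue_templates()
    serial = 1
    for i, res in enumerate(seq3):
        order = ["N", "CA", "C", "O"] + [
            nm for nm in _side_chain_order(templates[res]) if nm in pos[i]]
        for nm in order:
            element = nm[0]  # heavy-atom names start with their element here
            residues[i].atoms.append(AtomRecord(
                serial=serial, name=nm, element=element, coords=pos[i][nm]))
            serial += 1

    model = StructureModel(residues, source_format="synthetic",
                           structure_id=f"fixture_{spec.sequence}")
    model.fixture_spec = spec
    build_covalent_graph(model)
    return model


def _side_chain_order(tpl: dict) -> list[str]:
    seen, order = {"N", "CA", "C", "O"}, []
    for a1, a2 in tpl["heavy_bonds"]:
        for nm in (a1, a2):
            if nm not in seen:
                order.append(nm)
                seen.add(nm)
    return order


def _children_map(res: str) -> dict[str, list[str]]:
    """Side-chain tree (parent -> children) rooted at CA."""
    tpl = _data.residue_templates()[res]
    adj: dict[str, set[str]] = {}
    for a1, a2 in tpl["heavy_bonds"]:
        adj.setdefault(a1, set()).add(a2)
        adj.setdefault(a2, set()).add(a1)
    children: dict[str, list[str]] = {}
    seen = {"N", "C", "O", "CA"}
    frontier = ["CA"]
    while frontier:
        p = frontier.pop(0)
        kids = sorted(adj.get(p, set()) - seen)
        children[p] = kids
        seen.update(kids)
        frontier.extend(kids)
    return children


def _build_side_chain(T: _NoisyTargets, res: str, pos: dict[str, np.ndarray],
                      chi_default: float, prev_c: np.ndarray | None = None) -> None:
    children = _children_map(res)
    tree_parent = {"CA": None}
    for p, kids in children.items():
        for k in kids:
            tree_parent[k] = p

    ring = set(RING_ATOMS.get(res, []))
    placed_branches: dict[str, list[str]] = {}

    def frame_of(name: str) -> tuple[str, str]:
        """(grandparent, great-grandparent) names for a first branch."""
        p = tree_parent[name]
        g = tree_parent[p]
        if p == "CA":
            return "N", "C"           # CB handled specially below
        if g == "CA":
            return "CA", "N"
        return g, tree_parent[g]

    order = [k for p in children for k in children[p]]
    for name in order:
        if name in ring:
            continue
        p = tree_parent[name]
        sibs = placed_branches.setdefault(p, [])
        if p == "CA":
            # solve dihedral so N-CA-CB and C-CA-CB are both exact;
            # C sits at torsion 0 in the (C, N, CA) frame, L-config -> +dphi
            th_nc = T.angle(res, "N", "CA", "C")
            th_nb = T.angle(res, "N", "CA", name)
            th_cb = T.angle(res, name, "CA", "C")
            dphi = branch_dihedral(th_nc, th_nb, th_cb)
            pos[name] = place_atom(pos["C"], pos["N"], pos["CA"],
                                   T.bond(res, "CA", name), th_nb, dphi)
        elif not sibs:
            g, gg = frame_of(name)
            pos[name] = place_atom(pos[gg], pos[g], pos[p],
                                   T.bond(res, p, name),
                                   T.angle(res, g, p, name), chi_default)
        else:
            g, gg = frame_of(name)
            first = sibs[0]
            th_gf = T.angle(res, g, p, first)
            th_gx = T.angle(res, g, p, name)
            th_fx = T.angle(res, first, p, name)
            dphi = branch_dihedral(th_gf, th_gx, th_fx)
            phi_first = dihedral(pos[gg], pos[g], pos[p], pos[first])
            pos[name] = place_atom(pos[gg], pos[g], pos[p],
                                   T.bond(res, p, name), th_gx, phi_first - dphi)
        sibs.append(name)

    if ring:
        _build_ring(T, res, pos, chi_default)
    if res == "PRO":
        _refine_pro_ring(T, pos, prev_c)


def _ring_topology(res: str) -> tuple[list[str], list[tuple[str, str]]]:
    tpl = _data.residue_templates()[res]
    members = ["CB", "CG"] + RING_ATOMS[res]
    mset = set(members)
    bonds = [(a1, a2) for a1, a2 in tpl["heavy_bonds"] if a1 in mset and a2 in mset]
    return members, bonds


def _build_ring(T: _NoisyTargets, res: str, pos: dict[str, np.ndarray],
                chi2: float) -> None:
    """Planar ring system: 2D least-squares fit against the targets, then
    rigid embedding through CB-CG with torsion ``chi2`` for the first ring
    atom."""
    members, bonds = _ring_topology(res)
    free = [m for m in members if m not in ("CB", "CG")]
    d_bg = float(np.linalg.norm(pos["CG"] - pos["CB"]))
    fixed2d = {"CB": np.zeros(2), "CG": np.array([d_bg, 0.0])}

    # target list: every ring bond/angle with a table entry
    bond_t = [(a1, a2, T.bond(res, a1, a2)) for a1, a2 in bonds
              if (a1, a2) != ("CB", "CG") and (a2, a1) != ("CB", "CG")]
    adj: dict[str, set[str]] = {}
    for a1, a2 in bonds:
        adj.setdefault(a1, set()).add(a2)
        adj.setdefault(a2, set()).add(a1)
    angle_t = []
    for center, nbrs in adj.items():
        for x, y in itertools.combinations(sorted(nbrs), 2):
            tgt = T.targets.angle(res, x, center, y)
            if tgt is not None:
                angle_t.append((x, center, y, T.angle(res, x, center, y)))

    # initial guess: canonical planar ring coordinates (CB at origin, CG on
    # the +x axis); close enough to the optimum for every ring residue
    guess = dict(fixed2d)
    canon = _CANONICAL_RING_2D[res]
    scale = d_bg / 1.50
    for nm in free:
        guess[nm] = np.array(canon[nm]) * scale

    def coords_of(x):
        c = dict(fixed2d)
        for k, nm in enumerate(free):
            c[nm] = x[2 * k:2 * k + 2]
        return c

    def residuals(x):
        c = coords_of(x)
        out = []
        for a1, a2, tgt in bond_t:
            out.append(float(np.linalg.norm(c[a1] - c[a2])) - tgt)
        for a1, a2, a3, tgt in angle_t:
            u, w = c[a1] - c[a2], c[a3] - c[a2]
            cosv = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
            obs = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
            out.append(0.02 * (obs - tgt))  # ~deg-to-Angstrom weighting
        return out

    x0 = np.concatenate([guess[nm] for nm in free])
    fit = least_squares(residuals, x0, method="lm", max_nfev=2000)
    c2d = coords_of(fit.x)

    # embed: first ring atom placed by torsion chi2 about CB-CG
    first = RING_ATOMS[res][0]
    d_first = float(np.linalg.norm(c2d[first] - fixed2d["CG"]))
    u, w = c2d["CB"] - c2d["CG"], c2d[first] - c2d["CG"]
    th_first = np.degrees(np.arccos(np.clip(
        np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)), -1, 1)))
    first3d = place_atom(pos["CA"], pos["CB"], pos["CG"], d_first, th_first, chi2)
    ex = unit(pos["CG"] - pos["CB"])
    y_first = c2d[first][1]
    if abs(y_first) < 1e-9:
        raise RuntimeError("degenerate ring fit")
    ey = (first3d - pos["CB"] - c2d[first][0] * ex) / y_first
    for nm in free:
        pos[nm] = pos["CB"] + c2d[nm][0] * ex + c2d[nm][1] * ey


def _refine_pro_ring(T: _NoisyTargets, pos: dict[str, np.ndarray],
                     prev_c: np.ndarray | None = None) -> None:
    """Least-squares refinement of the proline CB/CG/CD positions in 3D."""
    res = "PRO"
    var = ["CB", "CG", "CD"]
    # start from a ring-like guess (chi1 ~ +30, chi2 ~ -35) so the fit closes
    pos["CG"] = place_atom(pos["N"], pos["CA"], pos["CB"], 1.492, 104.5, 30.0)
    pos["CD"] = place_atom(pos["CA"], pos["CB"], pos["CG"], 1.503, 106.1, -35.0)

    angle_keys = [("CA", "CB", "CG"), ("CB", "CG", "CD"), ("CG", "CD", "N"),
                  ("CD", "N", "CA"), ("N", "CA", "CB"), ("CB", "CA", "C")]
    if prev_c is not None:
        angle_keys.append(("-C", "N", "CD"))

    def residuals(x):
        c = {nm: x[3 * k:3 * k + 3] for k, nm in enumerate(var)}
        c.update({nm: pos[nm] for nm in ("N", "CA", "C")})
        if prev_c is not None:
            c["-C"] = prev_c
        out = []
        for a1, a2 in (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")):
            out.append(float(np.linalg.norm(c[a1] - c[a2]))
                       - T.targets.bond(res, a1, a2)[0])
        for a1, a2, a3 in angle_keys:
            u, w = c[a1] - c[a2], c[a3] - c[a2]
            cosv = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
            obs = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
            out.append(0.02 * (obs - T.targets.angle(res, a1, a2, a3)[0]))
        return out

    x0 = np.concatenate([pos[nm] for nm in var])
    fit = least_squares(residuals, x0, method="lm", max_nfev=2000)
    for k, nm in enumerate(var):
        pos[nm] = fit.x[3 * k:3 * k + 3]


# ---------------------------------------------------------------------------
# contact injection
# ---------------------------------------------------------------------------

def _resolve_selector(model: StructureModel, selector: str) -> AtomRecord:
    chain, seq, name = selector.split(":")
    for res in model.residues:
        if res.chain_id == chain and res.seq_number == int(seq):
            atom = res.get_atom(name)
            if atom is not None:
                return atom
    raise KeyError(f"selector {selector!r} matches no atom")


def _finding_keys(report) -> set[tuple]:
    keys = set()
    for f in report.findings:
        k = tuple(sorted([(id(f.atom_a)), id(f.atom_b)]))
        keys.add(k)
    return keys


def inject_contact(model: StructureModel, selector_a: str, selector_b: str,
                   ratio: float, table: VdwTable | None = None) -> StructureModel:
    """Rigidly translate the chain containing atom B so that
    d(A, B) = ratio * (r_A + r_B) exactly (primary radii).

    Raises ``ValueError`` if the move creates any close contact (ratio <=
    0.8 after exclusions) other than the engineered pair.  Works in place
    and returns the model.  Selector format: ``chain:resseq:atomname``.
    """
    table = table or VdwTable("primary")
    if not model.bonds:
        build_covalent_graph(model)
    before = detect_clashes(model, table=table)
    before_keys = {frozenset((f.atom_a.index, f.atom_b.index)) for f in before.findings}

    a = _resolve_selector(model, selector_a)
    b = _resolve_selector(model, selector_b)
    target = ratio * (table.radius_of(a) + table.radius_of(b))
    u = unit(b.coords - a.coords)
    shift = (target - float(np.linalg.norm(b.coords - a.coords))) * u
    chain_b = model.residue_of(b.index).chain_id
    for res in model.residues:
        if res.chain_id == chain_b:
            for atom in res.atoms:
                atom.coords = atom.coords + shift

    after = detect_clashes(model, table=table)
    after_keys = {frozenset((f.atom_a.index, f.atom_b.index)) for f in after.findings}
    engineered = {frozenset((a.index, b.index))}
    unintended = after_keys - before_keys - engineered
    if unintended:
        atoms = model.atoms()
        detail = [
            f"{model.residue_of(i).label}.{atoms[i].name}"
            f"--{model.residue_of(j).label}.{atoms[j].name}"
            f"@{np.linalg.norm(atoms[i].coords - atoms[j].coords):.2f}"
            for i, j in (tuple(sorted(k)) for k in unintended)]
        raise ValueError(f"contact injection created unintended contacts: {detail}")
    return model


def contact_scene(n_residues: int, ratios: list[float],
                  seed: int = 0) -> StructureModel:
    """A scene with ``n_residues`` polymer residues and one engineered
    methyl H-H contact per entry of ``ratios`` (each between a dedicated pair
    of single-alanine chains, far from everything else)."""
    n_probe = 2 * len(ratios)
    if n_residues <= n_probe:
        raise ValueError("n_residues too small for the requested contacts")
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    main = build_ideal_peptide(FixtureSpec("A" * (n_residues - n_probe), seed=seed))
    residues = list(main.residues)

    table = VdwTable("primary")
    for k, ratio in enumerate(ratios):
        offset = np.array([0.0, 60.0 + 30.0 * k, 0.0])
        pair_res = []
        for half in range(2):
            cid = chains[1 + 2 * k + half]
            probe = build_ideal_peptide(FixtureSpec("A", chain_id=cid, seed=seed))
            place_riding_hydrogens(probe)
            res = probe.residues[0]
            if half == 0:
                for atom in res.atoms:
                    atom.coords = atom.coords + offset
            else:
                partner = pair_res[0]
                hb1_a = partner.get_atom("HB1").coords
                u = unit(hb1_a - partner.get_atom("CB").coords)
                cb = res.get_atom("CB")
                hb1 = res.get_atom("HB1")
                axis = np.cross(unit(hb1.coords - cb.coords), -u)
                if np.linalg.norm(axis) < 1e-6:
                    axis = unit(np.cross(u, [1.0, 0.0, 0.0])
                                if abs(u[0]) < 0.9 else np.cross(u, [0.0, 1.0, 0.0]))
                ang0 = np.degrees(np.arccos(np.clip(
                    np.dot(unit(hb1.coords - cb.coords), -u), -1, 1)))
                pts0 = np.array([a.coords for a in res.atoms])
                pts0 = rotate_points(pts0, hb1.coords, axis, ang0)  # methyl faces -u
                # choose the roll about the contact axis that keeps every
                # non-engineered pair as far (in vdW-ratio terms) as possible
                target_d = ratio * 2.0 * table.radius("H")
                a_info = [(a.coords, table.radius_of(a)) for a in partner.atoms]
                hb1_idx = [a.name for a in res.atoms].index("HB1")
                best_roll, best_margin = 0.0, -np.inf
                for roll in range(0, 360, 15):
                    pts = rotate_points(pts0, pts0[hb1_idx], u, float(roll))
                    pts = pts + (hb1_a + target_d * u - pts[hb1_idx])
                    margin = np.inf
                    for bi, (atom, p) in enumerate(zip(res.atoms, pts)):
                        rb = table.radius_of(atom)
                        for ai, (pa, ra) in enumerate(a_info):
                            if bi == hb1_idx and partner.atoms[ai].name == "HB1":
                                continue
                            margin = min(margin,
                                         float(np.linalg.norm(p - pa)) / (ra + rb))
                    if margin > best_margin:
                        best_roll, best_margin = float(roll), margin
                pts = rotate_points(pts0, pts0[hb1_idx], u, best_roll)
                pts = pts + (hb1_a + 3.0 * u - pts[hb1_idx])
                for atom, p in zip(res.atoms, pts):
                    atom.coords = p
            pair_res.append(res)
            residues.append(res)

    model = StructureModel(residues, source_format="synthetic",
                           structure_id="contact_scene")
    build_covalent_graph(model)
    place_riding_hydrogens(model)
    for k, ratio in enumerate(ratios):
        ca, cb = chains[1 + 2 * k], chains[2 + 2 * k]
        inject_contact(model, f"{ca}:1:HB1", f"{cb}:1:HB1", ratio)
    return model


# ---------------------------------------------------------------------------
# geometry perturbation
# ---------------------------------------------------------------------------

def perturb_geometry(model: StructureModel, bond_k: float = 0.0,
                     angle_k: float = 0.0, seed: int | None = None) -> StructureModel:
    """Rebuild a fixture-built model with Gaussian internal-coordinate noise
    of ``k * sigma`` per bond/angle; expected RMS Z equals k.  The noise draw
    depends only on the seed, so doubling k exactly doubles every
    perturbation."""
    spec = model.fixture_spec
    if spec is None:
        raise ValueError("perturb_geometry requires a fixture-built model")
    new_spec = replace(spec, bond_noise_k=bond_k, angle_noise_k=angle_k,
                       seed=spec.seed if seed is None else seed)
    return build_ideal_peptide(new_spec)


# ---------------------------------------------------------------------------
# hydrogen-bond network toys
# ---------------------------------------------------------------------------

def enumerate_optimum(cluster: NetworkCluster, model: StructureModel,
                      params: NetworkParams | None = None) -> NetworkSolution:
    """Independent brute-force enumeration over the full state product."""
    params = params or NetworkParams()
    best = None
    for assignment in itertools.product(*(range(len(sp.states)) for sp in cluster.species)):
        sol = score_solution(cluster, assignment, model, params)
        if best is None or sol.score > best.score:
            best = sol
    return best


def _add_water(model: StructureModel, position: np.ndarray, seq: int) -> None:
    res = ResidueUnit("W", seq, "", "HOH", is_polymer=False, is_water=True)
    res.atoms.append(AtomRecord(serial=0, name="O", element="O",
                                coords=np.asarray(position, float)))
    model.residues.append(res)
    model.reindex()


def _add_acceptor_probe(model: StructureModel, target: np.ndarray,
                        away_from: np.ndarray, chain_id: str) -> None:
    """Single-alanine chain whose backbone O sits at ``target`` with the rest
    of the residue trailing away from ``away_from``."""
    probe = build_ideal_peptide(FixtureSpec("A", chain_id=chain_id))
    res = probe.residues[0]
    o, c = res.get_atom("O"), res.get_atom("C")
    # align O-C with the outward direction so the residue trails away
    v = unit(away_from - target)
    u0 = unit(o.coords - c.coords)
    axis = np.cross(u0, v)
    if np.linalg.norm(axis) < 1e-8:
        axis = np.array([0.0, 0.0, 1.0])
        ang = 0.0 if np.dot(u0, v) > 0 else 180.0
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(u0, v), -1, 1)))
    pts = np.array([a.coords for a in res.atoms])
    pts = rotate_points(pts, o.coords, axis, ang)
    shift = target - pts[[a.name for a in res.atoms].index("O")]
    for atom, p in zip(res.atoms, pts):
        atom.coords = p + shift
    model.residues.append(res)
    model.reindex()


def build_network_toy(kind: str, seed: int = 0,
                      params: NetworkParams | None = None,
                      ) -> tuple[StructureModel, list[tuple[tuple[str, ...], NetworkSolution]]]:
    """Small engineered scene plus its exhaustively enumerated optimum.

    Returns ``(model, [(species labels, optimum solution), ...])`` with one
    entry per cluster.  Kinds: ``singleton``, ``ser_water_chain``,
    ``asn_flip``, ``his_tautomer``, ``mixed``.
    """
    params = params or NetworkParams()
    geo = _data.h_geometry()

    if kind in ("singleton", "ser_water_chain", "mixed"):
        model = build_ideal_peptide(FixtureSpec("ASA", seed=seed))
        place_riding_hydrogens(model)
        res = model.residues[1]
        ca, cb, og = (res.get_atom(n).coords for n in ("CA", "CB", "OG"))
        h60 = place_atom(ca, cb, og, geo["bond_lengths"]["O"],
                         geo["angles"]["hydroxyl"], 60.0)
        u = unit(h60 - og)
        if kind == "singleton":
            _add_acceptor_probe(model, og + 2.8 * u, og, "P")
        else:
            _add_water(model, og + 2.8 * u, 1)
            _add_water(model, og + 2.8 * u + 2.8 * unit(u + np.array([0.25, 0.0, 0.1])), 2)
    elif kind == "asn_flip":
        # chi chosen so the amide clears its own backbone in both flip states
        model = build_ideal_peptide(FixtureSpec("ANA", chi=90.0, seed=seed))
        place_riding_hydrogens(model)
        res = model.residues[1]
        cb, cg = res.get_atom("CB"), res.get_atom("CG")
        names = ["OD1", "ND2", "HD21", "HD22"]
        pts = np.array([res.get_atom(n).coords for n in names])
        flipped = rotate_points(pts, cb.coords, cg.coords - cb.coords, 180.0)
        nd2_f = flipped[1]
        for k, hidx in enumerate((2, 3)):
            h_f = flipped[hidx]
            target = nd2_f + 2.9 * unit(h_f - nd2_f)
            _add_acceptor_probe(model, target, nd2_f, "PQ"[k])
    elif kind == "his_tautomer":
        model = build_ideal_peptide(FixtureSpec("AHA", seed=seed))
        place_riding_hydrogens(model)
        res = model.residues[1]
        ne2, cd2, ce1 = (res.get_atom(n).coords for n in ("NE2", "CD2", "CE1"))
        direction = unit(-(unit(cd2 - ne2) + unit(ce1 - ne2)))
        _add_acceptor_probe(model, ne2 + 2.9 * direction, ne2, "P")
    else:
        raise ValueError(f"unknown toy kind {kind!r}")

    build_covalent_graph(model)
    place_riding_hydrogens(model)
    species = find_variable_species(model, params)
    clusters = build_clusters(species, params.coupling_cutoff)
    optima = []
    for cluster in clusters:
        sol = enumerate_optimum(cluster, model, params)
        optima.append((tuple(sp.label for sp in cluster.species), sol))
    return model, optima
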