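"""Summary molecular-geometry statistics.

Bond-length/angle deviations are measured against a packaged table of ideal
values with standard deviations (Engh-Huber-style single-target set, lightly
adjusted so planar-centre angle triples are internally consistent); RMS Z
scores express deviations in units of the reference sigma.  Side-chain
planarity uses least-squares plane fits, and peptide omega angles are
measured against their trans/cis ideals.  Hydrogens are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clashaudit import data as _data
from clashaudit._vec import angle, dihedral, fit_plane
from clashaudit.structure_model import STANDARD_AA, StructureModel

PEPTIDE_BREAK = 2.5  # Angstrom; larger C-N distances are chain breaks


class GeometryTargets:
    """Lookup of ideal bond/angle values.

    Keys use atom names with a ``+``/``-`` prefix for atoms in the next or
    previous residue; residue ``"*"`` is the generic fallback.
    """

    def __init__(self, raw: dict | None = None):
        raw = raw or _data.geometry_targets_raw()
        self._bonds: dict[tuple[str, tuple[str, str]], tuple[float, float]] = {}
        self._angles: dict[tuple[str, tuple[str, str, str]], tuple[float, float]] = {}
        for rec in raw["bonds"]:
            a1, a2 = rec["atoms"]
            for key in ((a1, a2), (a2, a1)):
                self._bonds[(rec["res"], key)] = (rec["ideal"], rec["sigma"])
        for rec in raw["angles"]:
            a1, a2, a3 = rec["atoms"]
            for key in ((a1, a2, a3), (a3, a2, a1)):
                self._angles[(rec["res"], key)] = (rec["ideal"], rec["sigma"])
        if any(s <= 0 for _, s in list(self._bonds.values()) + list(self._angles.values())):
            raise ValueError("all target sigmas must be positive")
        self.planar_groups = {
            res: tpl["planar_groups"]
            for res, tpl in _data.residue_templates().items() if tpl["planar_groups"]
        }

    def bond(self, res_name: str, a1: str, a2: str) -> tuple[float, float] | None:
        return (self._bonds.get((res_name, (a1, a2)))
                or self._bonds.get(("*", (a1, a2))))

    def angle(self, res_name: str, a1: str, a2: str, a3: str) -> tuple[float, float] | None:
        return (self._angles.get((res_name, (a1, a2, a3)))
                or self._angles.get(("*", (a1, a2, a3))))


@dataclass
class GeometrySummary:
    bond_rmsd: float | None = None
    angle_rmsd: float | None = None
    bond_rmsz: float | None = None
    angle_rmsz: float | None = None
    planarity_rmsd: float | None = None
    omega_sd: float | None = None
    cis_fraction: float | None = None
    n_bonds: int = 0
    n_angles: int = 0
    n_planar_groups: int = 0
    n_omega: int = 0
    n_skipped_residues: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# deviation collection
# ---------------------------------------------------------------------------

def _relative_name(model: StructureModel, center_res: int, atom_index: int) -> str | None:
    """Atom name with +/- prefix relative to the residue holding the angle
    centre; None if more than one residue away."""
    ri = model.residue_index_of(atom_index)
    name = model.atoms()[atom_index].name
    if ri == center_res:
        return name
    if ri == center_res + 1:
        return "+" + name
    if ri == center_res - 1:
        return "-" + name
    return None


def bond_angle_deviations(model: StructureModel, targets: GeometryTargets | None = None,
                          ) -> tuple[list[tuple[float, float, float]],
                                     list[tuple[float, float, float]],
                                     int]:
    """Lists of (observed, ideal, sigma) for every covalent bond and angle
    with a target; hydrogens excluded, nonstandard residues skipped (their
    count is the third return value)."""
    targets = targets or GeometryTargets()
    atoms = model.atoms()
    skipped = {i for i, res in enumerate(model.residues)
               if not res.is_polymer or res.res_name not in STANDARD_AA}

    bond_devs: list[tuple[float, float, float]] = []
    for pair in sorted(model.bonds, key=lambda p: tuple(sorted(p))):
        i, j = sorted(pair)
        a, b = atoms[i], atoms[j]
        if a.is_hydrogen or b.is_hydrogen:
            continue
        ri, rj = model.residue_index_of(i), model.residue_index_of(j)
        if ri in skipped or rj in skipped:
            continue
        if ri == rj:
            tgt = targets.bond(model.residues[ri].res_name, a.name, b.name)
        else:
            lo = min(ri, rj, key=lambda r: r)
            n1 = _relative_name(model, lo, i)
            n2 = _relative_name(model, lo, j)
            if n1 is None or n2 is None:
                continue
            tgt = targets.bond(model.residues[lo].res_name, n1, n2)
        if tgt is None:
            continue
        obs = float(np.linalg.norm(a.coords - b.coords))
        bond_devs.append((obs, tgt[0], tgt[1]))

    angle_devs: list[tuple[float, float, float]] = []
    for j in range(model.n_atoms()):
        center = atoms[j]
        if center.is_hydrogen:
            continue
        rj = model.residue_index_of(j)
        if rj in skipped:
            continue
        nbrs = sorted(k for k in model.bonded(j) if not atoms[k].is_hydrogen)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                if model.residue_index_of(i) in skipped or model.residue_index_of(k) in skipped:
                    continue
                n1 = _relative_name(model, rj, i)
                n3 = _relative_name(model, rj, k)
                if n1 is None or n3 is None:
                    continue
                tgt = targets.angle(model.residues[rj].res_name, n1, center.name, n3)
                if tgt is None:
                    continue
                obs = angle(atoms[i].coords, center.coords, atoms[k].coords)
                angle_devs.append((obs, tgt[0], tgt[1]))

    return bond_devs, angle_devs, len(skipped)


def _deltas(deviations) -> np.ndarray:
    arr = np.asarray(deviations, dtype=float)
    if arr.ndim == 2:
        return arr[:, 0] - arr[:, 1]
    return arr


def rmsd(deviations) -> float | None:
    """Root-mean-square of deviations.  Accepts plain deltas or
    (observed, ideal[, sigma]) tuples; empty input gives None."""
    d = _deltas(deviations)
    if d.size == 0:
        return None
    return float(np.sqrt(np.mean(d ** 2)))


def rms_z(deviations) -> float | None:
    """Root-mean-square Z score; input is (observed, ideal, sigma) tuples or
    (delta, sigma) pairs."""
    arr = np.asarray(deviations, dtype=float)
    if arr.size == 0:
        return None
    if arr.ndim != 2:
        raise ValueError("rms_z requires (delta, sigma) or (obs, ideal, sigma) rows")
    if arr.shape[1] == 3:
        z = (arr[:, 0] - arr[:, 1]) / arr[:, 2]
    else:
        z = arr[:, 0] / arr[:, 1]
    return float(np.sqrt(np.mean(z ** 2)))


# ---------------------------------------------------------------------------
# planarity and omega
# ---------------------------------------------------------------------------

def sidechain_planarity(model: StructureModel, targets: GeometryTargets | None = None,
                        ) -> tuple[float | None, list[float]]:
    """Mean (and per-group list of) RMS distance of planar-group atoms from
    their least-squares plane.  Groups with fewer than four atoms present are
    skipped."""
    targets = targets or GeometryTargets()
    group_rmsds: list[float] = []
    for res in model.residues:
        for group in targets.planar_groups.get(res.res_name, []):
            coords = [a.coords for name in group for a in [res.get_atom(name)] if a is not None]
            if len(coords) < 4:
                continue
            pts = np.array(coords)
            centroid, normal = fit_plane(pts)
            dist = (pts - centroid) @ normal
            group_rmsds.append(float(np.sqrt(np.mean(dist ** 2))))
    if not group_rmsds:
        return None, []
    return float(np.mean(group_rmsds)), group_rmsds


def _wrap(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


def omega_stats(model: StructureModel) -> tuple[float | None, int, float | None]:
    """(omega_sd, n_peptides, cis_fraction).

    omega = CA(i)-C(i)-N(i+1)-CA(i+1); each peptide is assigned to trans
    (ideal 180) or cis (ideal 0) by proximity and the deviation taken
    circularly about the assigned ideal.  Chain breaks (C-N > 2.5 A) are
    skipped."""
    devs: list[float] = []
    n_cis = 0
    polymer = [r for r in model.residues if r.is_polymer]
    for r1, r2 in zip(polymer, polymer[1:]):
        if r1.chain_id != r2.chain_id:
            continue
        ca1, c1 = r1.get_atom("CA"), r1.get_atom("C")
        n2, ca2 = r2.get_atom("N"), r2.get_atom("CA")
        if None in (ca1, c1, n2, ca2):
            continue
        if float(np.linalg.norm(c1.coords - n2.coords)) > PEPTIDE_BREAK:
            continue
        omega = dihedral(ca1.coords, c1.coords, n2.coords, ca2.coords)
        if abs(_wrap(omega)) <= 90.0:   # cis
            devs.append(_wrap(omega))
            n_cis += 1
        else:                           # trans
            devs.append(_wrap(omega - 180.0))
    if not devs:
        return None, 0, None
    sd = float(np.sqrt(np.mean(np.asarray(devs) ** 2)))
    return sd, len(devs), n_cis / len(devs)


def geometry_summary(model: StructureModel, targets: GeometryTargets | None = None,
                     ) -> GeometrySummary:
    """Assemble all summary statistics for one model."""
    targets = targets or GeometryTargets()
    bond_devs, angle_devs, skipped = bond_angle_deviations(model, targets)
    planarity, groups = sidechain_planarity(model, targets)
    omega_sd, n_omega, cis_fraction = omega_stats(model)
    return GeometrySummary(
        bond_rmsd=rmsd(bond_devs),
        angle_rmsd=rmsd(angle_devs),
        bond_rmsz=rms_z(bond_devs) if bond_devs else None,
        angle_rmsz=rms_z(angle_devs) if angle_devs else None,
        planarity_rmsd=planarity,
        omega_sd=omega_sd,
        cis_fraction=cis_fraction,
        n_bonds=len(bond_devs),
        n_angles=len(angle_devs),
        n_planar_groups=len(groups),
        n_omega=n_omega,
        n_skipped_residues=skipped,
    )
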