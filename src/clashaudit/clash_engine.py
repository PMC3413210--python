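"""Nonbonded close-contact detection and classification.

Primary mode: a pair is a *clash* when its center-to-center distance is at
most 0.8 times the sum of the two van der Waals radii (Rowland-Taylor table,
H = 1.1 A) and a *severe clash* at 0.7 times that sum or less; boundaries are
inclusive and the classes disjoint.  A comparison mode implements the
Richardson-system definition (surface overlap >= 0.4 A with 1.00/1.17 A
hydrogen radii).

Hydrogen bonds are removed from consideration conservatively: every heavy
donor-acceptor pair (and donor hydrogens against acceptors) is excluded by
role alone, as are pairs within three covalent bonds.  Waters are tallied
separately and excluded from headline counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from clashaudit import data as _data
from clashaudit.structure_model import AtomRecord, StructureModel, residue_count

logger = logging.getLogger(__name__)

CLASH_RATIO = 0.8
SEVERE_RATIO = 0.7
RICHARDSON_OVERLAP = 0.4
BONDED_PATH_DEPTH = 3  # 1-2, 1-3 and 1-4 pairs are excluded


class UnknownElementError(KeyError):
    pass


class VdwTable:
    """Element -> van der Waals radius, in the primary (Rowland-Taylor) or
    Richardson dialect.  Unlisted elements fall back to Bondi values with a
    warning."""

    def __init__(self, mode: str = "primary", overrides: dict[str, float] | None = None):
        if mode not in ("primary", "richardson"):
            raise ValueError(f"unknown mode {mode!r}")
        tables = _data.vdw_tables()
        self.mode = mode
        self._primary = dict(tables["primary"])
        self._bondi = dict(tables["bondi"])
        self._richardson = dict(tables["richardson"])
        if overrides:
            target = self._primary if mode == "primary" else self._richardson
            target.update({k.upper(): float(v) for k, v in overrides.items()})
        for table in (self._primary, self._bondi, self._richardson):
            if any(v <= 0 for v in table.values()):
                raise ValueError("all radii must be positive")
        self._warned: set[str] = set()

    @classmethod
    def from_file(cls, path: str, mode: str = "primary") -> "VdwTable":
        """Simple ``element radius`` two-column text file."""
        overrides = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if line:
                    el, r = line.split()
                    overrides[el] = float(r)
        return cls(mode, overrides)

    def radius(self, element: str, polar_aromatic_h: bool = False) -> float:
        element = element.upper()
        if self.mode == "richardson":
            if element == "H":
                return self._richardson["H_POLAR" if polar_aromatic_h else "H_OTHER"]
            if element in self._richardson:
                return self._richardson[element]
        elif element in self._primary:
            return self._primary[element]
        if element in self._bondi:
            if element not in self._warned:
                logger.warning("element %s not in %s table; using Bondi radius",
                               element, self.mode)
                self._warned.add(element)
            return self._bondi[element]
        raise UnknownElementError(f"no van der Waals radius for element {element!r}")

    def radius_of(self, atom: AtomRecord) -> float:
        return self.radius(atom.element, atom.polar_aromatic_h)

    def max_radius(self) -> float:
        vals = list(self._primary.values()) + list(self._bondi.values())
        if self.mode == "richardson":
            vals += list(self._richardson.values())
        return max(vals)


def vdw_radius(element: str, mode: str = "primary", polar_aromatic_h: bool = False) -> float:
    """Convenience lookup against a default table."""
    return VdwTable(mode).radius(element, polar_aromatic_h)


@dataclass
class ClashFinding:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    sum_radii: float
    clash_class: str       # "severe" | "clash" | "none"
    ratio: float | None = None     # primary mode
    overlap: float | None = None   # richardson mode
    involves_water: bool = False
    exclusion_reason: str | None = None


@dataclass
class ClashReport:
    mode: str
    findings: list[ClashFinding] = field(default_factory=list)
    water_findings: list[ClashFinding] = field(default_factory=list)
    excluded: dict[str, int] = field(default_factory=dict)
    n_clashes: int = 0
    n_severe: int = 0
    residue_count: int = 0
    clashes_per_100: float | None = None
    severe_per_100: float | None = None


# ---------------------------------------------------------------------------
# contact search
# ---------------------------------------------------------------------------

def find_contacts(model: StructureModel, cutoff: float) -> list[tuple[int, int]]:
    """All atom-index pairs (i < j) with distance <= cutoff (k-d tree)."""
    coords = model.coords()
    if len(coords) < 2:
        return []
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return [(int(i), int(j)) for i, j in pairs]


def classify_contact(atom_a: AtomRecord, atom_b: AtomRecord, table: VdwTable) -> ClashFinding:
    """Classify one pair against the threshold rule of ``table.mode``."""
    d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
    rsum = table.radius_of(atom_a) + table.radius_of(atom_b)
    eps = 1e-9  # boundaries are inclusive; guard against rounding
    if table.mode == "primary":
        ratio = d / rsum
        if ratio <= SEVERE_RATIO + eps:
            cls = "severe"
        elif ratio <= CLASH_RATIO + eps:
            cls = "clash"
        else:
            cls = "none"
        return ClashFinding(atom_a, atom_b, d, rsum, cls, ratio=ratio)
    overlap = rsum - d
    cls = "clash" if overlap >= RICHARDSON_OVERLAP - eps else "none"
    return ClashFinding(atom_a, atom_b, d, rsum, cls, overlap=overlap)


# ---------------------------------------------------------------------------
# donor / acceptor roles and exclusions
# ---------------------------------------------------------------------------

@dataclass
class HbondRoles:
    donors: set[int] = field(default_factory=set)       # heavy donor atoms
    acceptors: set[int] = field(default_factory=set)    # heavy acceptor atoms
    donor_hydrogens: set[int] = field(default_factory=set)


def assign_hbond_roles(model: StructureModel) -> HbondRoles:
    """Potential-hydrogen-bond roles, by template name plus hydrogen count.

    Donors are N/O/S carrying at least one hydrogen (or template-listed
    donors in united-atom models, where no hydrogen is present to witness the
    role).  Acceptors come from the template list; His ring nitrogens only
    accept while unprotonated.
    """
    templates = _data.residue_templates()
    any_h = any(a.is_hydrogen for a in model.atoms())
    roles = HbondRoles()
    for res in model.residues:
        tname = res.template_name()
        if tname is None:
            continue
        tpl = templates[tname]
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            attached_h = [j for j in model.bonded(atom.index)
                          if model.atoms()[j].is_hydrogen]
            is_template_donor = atom.name in tpl["donors"]
            if atom.element in ("N", "O", "S") and attached_h:
                roles.donors.add(atom.index)
                roles.donor_hydrogens.update(attached_h)
            elif is_template_donor and not any_h:
                roles.donors.add(atom.index)
            if atom.name in tpl["acceptors"]:
                if tname == "HIS" and atom.name in ("ND1", "NE2") and attached_h:
                    continue
                roles.acceptors.add(atom.index)
    return roles


def apply_exclusions(pairs: list[tuple[int, int]], model: StructureModel,
                     roles: HbondRoles | None = None,
                     ) -> tuple[list[tuple[int, int]], dict[str, int]]:
    """Drop pairs that cannot count as nonbonded clashes.

    Reasons (tallied): ``bonded_path`` (within 3 covalent bonds),
    ``donor_acceptor`` (potential hydrogen-bond heavy pair), ``donor_h``
    (donor-attached H against an acceptor, or two donor hydrogens whose
    parents are a donor/acceptor pair is *not* excluded), ``flip_group``
    (both atoms in one residue's amide/imidazole flip group) and ``altloc``
    (different non-blank conformer labels).
    """
    if roles is None:
        roles = assign_hbond_roles(model)
    atoms = model.atoms()
    templates = _data.residue_templates()
    kept: list[tuple[int, int]] = []
    tally = {"bonded_path": 0, "donor_acceptor": 0, "donor_h": 0,
             "flip_group": 0, "altloc": 0}
    for i, j in pairs:
        a, b = atoms[i], atoms[j]
        if a.altloc and b.altloc and a.altloc != b.altloc:
            tally["altloc"] += 1
            continue
        if model.bond_path_within(i, j, BONDED_PATH_DEPTH):
            tally["bonded_path"] += 1
            continue
        if (i in roles.donors and j in roles.acceptors) or \
           (j in roles.donors and i in roles.acceptors):
            tally["donor_acceptor"] += 1
            continue
        if (i in roles.donor_hydrogens and j in roles.acceptors) or \
           (j in roles.donor_hydrogens and i in roles.acceptors):
            tally["donor_h"] += 1
            continue
        res_i = model.residue_index_of(i)
        if res_i == model.residue_index_of(j):
            tpl = model.residues[res_i].template_name()
            flip = templates[tpl]["flip"] if tpl else None
            if flip and a.name in flip["atoms"] and b.name in flip["atoms"]:
                tally["flip_group"] += 1
                continue
        kept.append((i, j))
    return kept, tally


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def detect_clashes(model: StructureModel, mode: str = "primary",
                   table: VdwTable | None = None,
                   include_symmetry: bool = False) -> ClashReport:
    """Find, filter and classify all close contacts of a model.

    The model must have its covalent graph built and altlocs resolved.
    Contacts involving water are reported separately (``water_findings``)
    and excluded from the headline counts.  Symmetry mates are not generated
    (``include_symmetry`` is a stub and must stay False).
    """
    if include_symmetry:
        raise NotImplementedError("symmetry-expanded clash detection is out of scope")
    table = table or VdwTable(mode)
    cutoff = CLASH_RATIO * 2.0 * table.max_radius()
    pairs = find_contacts(model, cutoff)
    kept, tally = apply_exclusions(pairs, model)

    report = ClashReport(mode=table.mode)
    atoms = model.atoms()
    for i, j in kept:
        finding = classify_contact(atoms[i], atoms[j], table)
        if finding.clash_class == "none":
            continue
        res_a = model.residue_of(i)
        res_b = model.residue_of(j)
        finding.involves_water = res_a.is_water or res_b.is_water
        if finding.involves_water:
            report.water_findings.append(finding)
        else:
            report.findings.append(finding)

    report.excluded = tally
    report.n_clashes = sum(1 for f in report.findings if f.clash_class == "clash")
    report.n_severe = sum(1 for f in report.findings if f.clash_class == "severe")
    report.residue_count = residue_count(model)
    if report.residue_count > 0:
        report.clashes_per_100 = per_100(report.n_clashes, report.residue_count)
        report.severe_per_100 = per_100(report.n_severe, report.residue_count)
    return report


def per_100(count: int, residues: int) -> float:
    """Frequency per 100 residues, reported to one decimal."""
    if residues <= 0:
        raise ValueError("residue count must be positive")
    return round(100.0 * count / residues, 1)
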