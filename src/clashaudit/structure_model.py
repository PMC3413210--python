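"""Macromolecular structure data model and PDB/mmCIF I/O.

The containers are deliberately simple: a :class:`StructureModel` is an
ordered list of :class:`ResidueUnit` objects holding :class:`AtomRecord`
atoms, plus a covalent graph over global atom indices.  I/O is delegated to
biotite; coordinates are kept in the deposited orthogonal frame (no symmetry
expansion).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io import pdbx

from clashaudit import data as _data

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Common modified residues mapped onto a standard template for bonding purposes.
MODIFIED_AA_PARENT = {"MSE": "MET", "CSO": "CYS", "SEP": "SER", "TPO": "THR", "PTR": "TYR"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as PDB/mmCIF."""


class EmptyInputError(ValueError):
    """Raised when a structure file contains no atoms."""


@dataclass
class AtomRecord:
    """One atom as deposited (or as constructed)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hydrogen: bool = False
    polar_aromatic_h: bool = False
    #: global index within the owning model, maintained by ``StructureModel.reindex``
    index: int = -1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass
class ResidueUnit:
    """One residue (amino acid, water or other heterogroup)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_polymer: bool = False
    is_water: bool = False

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_number}{self.insertion_code.strip()}"

    def get_atom(self, name: str, altloc: str | None = None) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.name == name and (altloc is None or atom.altloc == altloc):
                return atom
        return None

    def get_atoms(self, name: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.name == name]

    def template_name(self) -> str | None:
        """Name of the residue template that applies (handles modified AAs)."""
        if self.res_name in _data.residue_templates():
            return self.res_name
        return MODIFIED_AA_PARENT.get(self.res_name)


class StructureModel:
    """Hierarchical atom container with a covalent graph."""

    def __init__(self, residues: list[ResidueUnit] | None = None,
                 resolution: float | None = None, source_format: str | None = None,
                 structure_id: str = ""):
        self.residues: list[ResidueUnit] = residues or []
        self.bonds: set[frozenset[int]] = set()
        self.adjacency: dict[int, set[int]] = {}
        self.resolution = resolution
        self.source_format = source_format
        self.structure_id = structure_id
        self.fixture_spec = None  # provenance hook used by the fixture generator
        self.reindex()

    # -- indexing ---------------------------------------------------------
    def reindex(self) -> None:
        self._atoms: list[AtomRecord] = []
        self._atom_residue: list[int] = []
        for ri, res in enumerate(self.residues):
            for atom in res.atoms:
                atom.index = len(self._atoms)
                self._atoms.append(atom)
                self._atom_residue.append(ri)

    def atoms(self) -> list[AtomRecord]:
        return self._atoms

    def n_atoms(self) -> int:
        return len(self._atoms)

    def residue_of(self, atom_index: int) -> ResidueUnit:
        return self.residues[self._atom_residue[atom_index]]

    def residue_index_of(self, atom_index: int) -> int:
        return self._atom_residue[atom_index]

    def coords(self) -> np.ndarray:
        if not self._atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self._atoms])

    # -- bonds ------------------------------------------------------------
    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            return
        self.bonds.add(frozenset((i, j)))
        self.adjacency.setdefault(i, set()).add(j)
        self.adjacency.setdefault(j, set()).add(i)

    def bonded(self, i: int) -> set[int]:
        return self.adjacency.get(i, set())

    def bond_path_within(self, i: int, j: int, max_depth: int) -> bool:
        """True if i and j are separated by at most ``max_depth`` bonds."""
        frontier = {i}
        seen = {i}
        for _ in range(max_depth):
            frontier = {n for f in frontier for n in self.bonded(f)} - seen
            if j in frontier:
                return True
            seen |= frontier
        return False

    def clear_bonds(self) -> None:
        self.bonds = set()
        self.adjacency = {}

    # -- copying ----------------------------------------------------------
    def copy(self) -> "StructureModel":
        residues = [
            ResidueUnit(r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                        [a.copy() for a in r.atoms], r.is_polymer, r.is_water)
            for r in self.residues
        ]
        model = StructureModel(residues, self.resolution, self.source_format,
                               self.structure_id)
        for pair in self.bonds:
            i, j = tuple(pair)
            model.add_bond(i, j)
        model.fixture_spec = self.fixture_spec
        return model


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    stripped = re.sub(r"[^A-Za-z]", "", name)
    if not stripped:
        return ""
    # Two-letter elements occurring in proteins/ligands when the first column
    # position indicates them; default to the chemically sensible single letter.
    if len(name) == 4 and name[0] in "123456789":  # e.g. 1HB2
        return stripped[0].upper()
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "CL", "BR", "SE", "NA", "CU", "NI", "CO", "CD", "HG"}:
        return two
    return stripped[0].upper()


def _polymer_flags(res_name: str, atom_names: set[str]) -> tuple[bool, bool]:
    is_water = res_name in WATER_NAMES
    if is_water:
        return False, True
    if res_name in STANDARD_AA or res_name in MODIFIED_AA_PARENT:
        return True, False
    # Modified residue heuristic: backbone atoms present.
    if {"N", "CA", "C"} <= atom_names:
        return True, False
    return False, False


def _from_atom_array(array: AtomArray, source_format: str,
                     resolution: float | None, structure_id: str) -> StructureModel:
    if array.array_length() == 0:
        raise EmptyInputError("structure contains no atoms")
    occupancy = (array.occupancy if "occupancy" in array.get_annotation_categories()
                 else np.ones(array.array_length()))
    b_factor = (array.b_factor if "b_factor" in array.get_annotation_categories()
                else np.zeros(array.array_length()))
    altloc = (array.altloc_id if "altloc_id" in array.get_annotation_categories()
              else np.full(array.array_length(), ""))
    serial = (array.atom_id if "atom_id" in array.get_annotation_categories()
              else np.arange(1, array.array_length() + 1))

    residues: list[ResidueUnit] = []
    key = None
    for i in range(array.array_length()):
        ins = str(array.ins_code[i]) if "ins_code" in array.get_annotation_categories() else ""
        rkey = (str(array.chain_id[i]), int(array.res_id[i]), ins, str(array.res_name[i]))
        if rkey != key:
            residues.append(ResidueUnit(rkey[0], rkey[1], rkey[2], rkey[3]))
            key = rkey
        element = str(array.element[i]).strip().upper() or _infer_element(str(array.atom_name[i]))
        alt = str(altloc[i]).strip().replace(".", "")
        occ = float(occupancy[i])
        atom = AtomRecord(
            serial=int(serial[i]),
            name=str(array.atom_name[i]).strip(),
            element=element,
            coords=np.array(array.coord[i], dtype=float),
            occupancy=min(max(occ, 0.0), 1.0),
            b_factor=float(b_factor[i]),
            altloc="" if alt in ("", " ") else alt,
            is_hydrogen=element in ("H", "D"),
        )
        residues[-1].atoms.append(atom)

    for res in residues:
        names = {a.name for a in res.atoms}
        res.is_polymer, res.is_water = _polymer_flags(res.res_name, names)
    return StructureModel(residues, resolution, source_format, structure_id)


def _pdb_resolution(path: str) -> float | None:
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("REMARK   2 RESOLUTION"):
                    m = re.search(r"(\d+\.\d+)\s+ANGSTROM", line)
                    if m:
                        return float(m.group(1))
    except OSError:
        pass
    return None


def _cif_resolution(cif) -> float | None:
    block = cif.block
    for cat, key in (("refine", "ls_d_res_high"), ("reflns", "d_resolution_high")):
        try:
            val = block[cat][key].as_item()
            return float(val)
        except (KeyError, ValueError, TypeError):
            continue
    return None


def read_structure(path: str, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first MODEL of a multi-model file is used (with a logged
    warning).  All alternate conformers are retained; use
    :func:`select_primary_altlocs` to resolve them.
    """
    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    structure_id = re.sub(r"\.(pdb|ent|cif|mmcif)$", "", path.rsplit("/", 1)[-1])

    extra = ["occupancy", "b_factor", "atom_id"]
    try:
        if fmt == "pdb":
            pdb = PDBFile.read(path)
            n_models = pdb.get_model_count()
            if n_models > 1:
                logger.warning("file %s has %d models; using the first", path, n_models)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                array = pdb.get_structure(model=1, altloc="all", extra_fields=extra)
            resolution = _pdb_resolution(path)
        elif fmt == "mmcif":
            cif = pdbx.CIFFile.read(path)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                array = pdbx.get_structure(cif, model=1, altloc="all", extra_fields=extra)
            resolution = _cif_resolution(cif)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except (EmptyInputError, FormatError):
        raise
    except Exception as exc:  # biotite raises a zoo of parse errors
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    return _from_atom_array(array, fmt, resolution, structure_id)


# ---------------------------------------------------------------------------
# altloc selection
# ---------------------------------------------------------------------------

def select_primary_altlocs(model: StructureModel) -> StructureModel:
    """Keep, per residue, only the alternate-conformer label with the highest
    occupancy (ties broken by file order); blank-altloc atoms are always kept.
    Returns a new model; idempotent."""
    out = model.copy()
    for res in out.residues:
        labels: list[str] = []
        occ_sum: dict[str, list[float]] = {}
        for atom in res.atoms:
            if atom.altloc:
                if atom.altloc not in occ_sum:
                    labels.append(atom.altloc)
                    occ_sum[atom.altloc] = []
                occ_sum[atom.altloc].append(atom.occupancy)
        if not labels:
            continue
        best = max(labels, key=lambda lab: (np.mean(occ_sum[lab]), -labels.index(lab)))
        res.atoms = [a for a in res.atoms if not a.altloc or a.altloc == best]
    out.clear_bonds()
    out.reindex()
    return out


# ---------------------------------------------------------------------------
# covalent graph
# ---------------------------------------------------------------------------

#: d <= DISTANCE_BOND_FACTOR * (r_i + r_j) is treated as a covalent bond for
#: residues without a template.
DISTANCE_BOND_FACTOR = 0.6
DISULFIDE_MAX = 2.5
PEPTIDE_MAX = 2.5
H_ATTACH_MAX = 1.6


def _primary_radius(element: str) -> float:
    tables = _data.vdw_tables()
    return tables["primary"].get(element, tables["bondi"].get(element, 1.7))


def _compatible_altloc(a: AtomRecord, b: AtomRecord) -> bool:
    return not a.altloc or not b.altloc or a.altloc == b.altloc


def build_covalent_graph(model: StructureModel) -> StructureModel:
    """Populate ``model.bonds`` in place (and return the model).

    Bonds come from per-residue templates for standard amino acids, peptide
    links, disulfides, N-terminal/OXT specials and a distance fallback for
    residues without a template.  Hydrogens not named in a template are
    attached to the nearest heavy atom within 1.6 Angstrom.
    """
    model.clear_bonds()
    templates = _data.residue_templates()

    for res in model.residues:
        tname = res.template_name()
        if tname is not None:
            tpl = templates[tname]
            # template heavy-atom bonds
            for n1, n2 in tpl["heavy_bonds"]:
                for a in res.get_atoms(n1):
                    for b in res.get_atoms(n2):
                        if _compatible_altloc(a, b):
                            model.add_bond(a.index, b.index)
            # OXT
            for a in res.get_atoms("OXT"):
                for b in res.get_atoms("C"):
                    if _compatible_altloc(a, b):
                        model.add_bond(a.index, b.index)
            # template hydrogens
            for parent, hnames in tpl["hydrogens"].items():
                for hname in hnames:
                    for h in res.get_atoms(hname):
                        for p in res.get_atoms(parent):
                            if _compatible_altloc(h, p):
                                model.add_bond(h.index, p.index)
            # N-terminal hydrogens H1/H2/H3 (and H on PRO N-terminus)
            for hname in ("H1", "H2", "H3", "H"):
                for h in res.get_atoms(hname):
                    if model.bonded(h.index):
                        continue
                    for p in res.get_atoms("N"):
                        if _compatible_altloc(h, p):
                            model.add_bond(h.index, p.index)
        else:
            # distance fallback within the residue
            atoms = res.atoms
            for i, a in enumerate(atoms):
                for b in atoms[i + 1:]:
                    if not _compatible_altloc(a, b):
                        continue
                    d = float(np.linalg.norm(a.coords - b.coords))
                    cut = DISTANCE_BOND_FACTOR * (_primary_radius(a.element)
                                                  + _primary_radius(b.element))
                    if d <= cut:
                        model.add_bond(a.index, b.index)

    # attach stray hydrogens (nonstandard names) to nearest heavy atom
    for res in model.residues:
        for h in res.atoms:
            if h.is_hydrogen and not model.bonded(h.index):
                best, best_d = None, H_ATTACH_MAX
                for p in res.atoms:
                    if p.is_hydrogen or not _compatible_altloc(h, p):
                        continue
                    d = float(np.linalg.norm(h.coords - p.coords))
                    if d < best_d:
                        best, best_d = p, d
                if best is not None:
                    model.add_bond(h.index, best.index)

    # peptide bonds between consecutive polymer residues of a chain
    prev = None
    for res in model.residues:
        if res.is_polymer:
            if prev is not None and prev.chain_id == res.chain_id:
                for c in prev.get_atoms("C"):
                    for n in res.get_atoms("N"):
                        if _compatible_altloc(c, n):
                            d = float(np.linalg.norm(c.coords - n.coords))
                            if d <= PEPTIDE_MAX:
                                model.add_bond(c.index, n.index)
            prev = res
        elif not res.is_water:
            prev = None

    # disulfides
    sg = [a for r in model.residues if r.template_name() == "CYS"
          for a in r.get_atoms("SG")]
    for i, a in enumerate(sg):
        for b in sg[i + 1:]:
            if float(np.linalg.norm(a.coords - b.coords)) <= DISULFIDE_MAX:
                model.add_bond(a.index, b.index)

    _assign_h_flags(model)
    return model


def _assign_h_flags(model: StructureModel) -> None:
    """Set ``polar_aromatic_h`` on every H atom: bonded to N/O/S or to an
    aromatic ring carbon."""
    templates = _data.residue_templates()
    for res in model.residues:
        tname = res.template_name()
        aromatic = set(templates[tname]["aromatic_c"]) if tname else set()
        for atom in res.atoms:
            if not atom.is_hydrogen:
                continue
            flag = False
            for j in model.bonded(atom.index):
                parent = model.atoms()[j]
                if parent.element in ("N", "O", "S"):
                    flag = True
                elif parent.name in aromatic:
                    flag = True
            atom.polar_aromatic_h = flag


# ---------------------------------------------------------------------------
# counting / writing
# ---------------------------------------------------------------------------

def residue_count(model: StructureModel) -> int:
    """Number of polymer amino-acid residues (waters and other heterogroups
    excluded)."""
    return sum(1 for r in model.residues if r.is_polymer)


def _to_atom_array(model: StructureModel) -> AtomArray:
    n = model.n_atoms()
    array = AtomArray(n)
    array.add_annotation("occupancy", float)
    array.add_annotation("b_factor", float)
    array.add_annotation("atom_id", int)
    i = 0
    for res in model.residues:
        for atom in res.atoms:
            array.chain_id[i] = res.chain_id or "A"
            array.res_id[i] = res.seq_number
            array.ins_code[i] = res.insertion_code.strip()
            array.res_name[i] = res.res_name
            array.hetero[i] = not res.is_polymer
            array.atom_name[i] = atom.name
            array.element[i] = atom.element
            array.coord[i] = atom.coords
            array.occupancy[i] = atom.occupancy
            array.b_factor[i] = atom.b_factor
            array.atom_id[i] = i + 1
            i += 1
    return array


def write_structure(model: StructureModel, path: str, fmt: str | None = None,
                    hybrid36: bool = False) -> None:
    """Write the model as PDB or mmCIF.

    PDB atom names longer than four characters raise a ``ValueError``.  Files
    with more than 99999 atoms require ``hybrid36=True`` in the PDB dialect.
    """
    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    array = _to_atom_array(model)
    if fmt == "pdb":
        for atom in model.atoms():
            if len(atom.name) > 4:
                raise ValueError(f"atom name {atom.name!r} too long for PDB format")
        if model.n_atoms() > 99999 and not hybrid36:
            raise ValueError("more than 99999 atoms: enable hybrid36 or write mmCIF")
        pdb = PDBFile()
        pdb.set_structure(array, hybrid36=hybrid36)
        pdb.write(path)
    elif fmt == "mmcif":
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, array, data_block=model.structure_id or "model")
        cif.write(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
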