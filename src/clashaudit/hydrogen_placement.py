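"""Classification of hydrogen sites and riding-hydrogen construction.

Hydrogens are placed at ideal nuclear geometry from the positions of the
non-H atoms; heavy-atom coordinates are never modified.  Rotatable hydrogens
(hydroxyl, sulfhydryl, phenolic, terminal amine, water) receive a
deterministic default orientation here and are refined by the hydrogen-bond
network optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from clashaudit import data as _data
from clashaudit._vec import place_atom, unit
from clashaudit.structure_model import (
    AtomRecord, ResidueUnit, StructureModel, build_covalent_graph,
)

logger = logging.getLogger(__name__)

#: (residue template, parent atom) -> rotatable kind
ROTATABLE_PARENTS = {
    ("SER", "OG"): "hydroxyl",
    ("THR", "OG1"): "hydroxyl",
    ("TYR", "OH"): "phenolic",
    ("CYS", "SG"): "sulfhydryl",
    ("LYS", "NZ"): "amine",
    ("HOH", "O"): "water",
}


@dataclass
class HydrogenSite:
    """All hydrogens riding on (or rotating about) one parent heavy atom."""

    parent_atom: AtomRecord
    residue: ResidueUnit
    h_names: list[str] = field(default_factory=list)
    site_class: str = "riding"          # riding | rotatable
    rotatable_kind: str = "none"        # hydroxyl|sulfhydryl|phenolic|amine|water|none
    torsion_axis: tuple[AtomRecord, AtomRecord] | None = None

    def __post_init__(self):
        if self.site_class == "riding":
            assert self.rotatable_kind == "none"
        elif self.rotatable_kind != "water" and self.torsion_axis is None:
            raise ValueError("rotatable site requires a torsion axis")


def _heavy_neighbors(model: StructureModel, atom: AtomRecord) -> list[AtomRecord]:
    out = [model.atoms()[j] for j in sorted(model.bonded(atom.index))]
    return [a for a in out if not a.is_hydrogen]


def classify_hydrogen_sites(model: StructureModel) -> list[HydrogenSite]:
    """One site per parent heavy atom that carries template hydrogens.

    Requires the covalent graph.  Sites whose frame atoms are missing are
    skipped with a warning.
    """
    templates = _data.residue_templates()
    sites: list[HydrogenSite] = []
    for res in model.residues:
        tname = res.template_name()
        if tname is None:
            continue
        tpl = templates[tname]
        for parent_name, h_names in tpl["hydrogens"].items():
            parent = res.get_atom(parent_name)
            if parent is None:
                continue
            kind = ROTATABLE_PARENTS.get((tname, parent_name))
            if kind is None:
                sites.append(HydrogenSite(parent, res, list(h_names), "riding", "none"))
            elif kind == "water":
                sites.append(HydrogenSite(parent, res, list(h_names), "rotatable", kind))
            else:
                heavies = _heavy_neighbors(model, parent)
                if not heavies:
                    logger.warning("no axis for rotatable site at %s %s; skipped",
                                   res.label, parent_name)
                    continue
                sites.append(HydrogenSite(parent, res, list(h_names), "rotatable",
                                          kind, (heavies[0], parent)))
    return sites


# ---------------------------------------------------------------------------
# placement geometry
# ---------------------------------------------------------------------------

def _h_length(parent_element: str) -> float:
    return _data.h_geometry()["bond_lengths"].get(parent_element, 1.090)


def _grandparent(model: StructureModel, base: AtomRecord, exclude: AtomRecord) -> AtomRecord | None:
    for a in _heavy_neighbors(model, base):
        if a.index != exclude.index:
            return a
    return None


def compute_h_positions(model: StructureModel, site: HydrogenSite,
                        torsion: float = 180.0) -> list[np.ndarray] | None:
    """Ideal positions for the hydrogens of ``site``.

    ``torsion`` sets the first H dihedral for rotatable and 3-fold sites.
    Returns ``None`` when frame atoms are missing.
    """
    geo = _data.h_geometry()["angles"]
    p = site.parent_atom
    length = _h_length(p.element)
    n_h = len(site.h_names)
    heavies = _heavy_neighbors(model, p)
    tpl = _data.residue_templates()[site.residue.template_name()]
    is_sp2 = p.name in tpl["sp2"]

    if site.rotatable_kind == "water":
        # deterministic default orientation; the network optimizer rotates it
        e1 = np.array([1.0, 0.0, 0.0])
        ang = np.radians(geo["water"])
        e2 = np.array([np.cos(ang), np.sin(ang), 0.0])
        return [p.coords + length * e1, p.coords + length * e2][:n_h]

    if not heavies:
        return None
    b = heavies[0]

    if n_h == 1 and len(heavies) == 1:
        # hydroxyl / sulfhydryl / phenolic: torsion about b-p
        g = _grandparent(model, b, p)
        if g is None:
            return None
        ang = {"sulfhydryl": geo["sulfhydryl"]}.get(site.rotatable_kind, geo["hydroxyl"])
        if is_sp2:
            ang = geo["sp2"]
        return [place_atom(g.coords, b.coords, p.coords, length, ang, torsion)]

    if n_h == 3:
        # methyl / ammonium: three-fold staggered about b-p
        g = _grandparent(model, b, p)
        if g is None:
            return None
        theta = geo["sp3"]
        return [place_atom(g.coords, b.coords, p.coords, length, theta, torsion + k * 120.0)
                for k in range(3)]

    if n_h == 1 and len(heavies) == 3:
        # tetrahedral CH: opposite the sum of the three substituent directions
        s = sum(unit(h.coords - p.coords) for h in heavies)
        return [p.coords + length * unit(-s)]

    if n_h == 1 and len(heavies) == 2:
        # in-plane (sp2: ring CH, amide NH) or out-of-plane-free sp3 -- both
        # use the anti-bisector; for sp2 this lies exactly in the heavy plane
        u1 = unit(heavies[0].coords - p.coords)
        u2 = unit(heavies[1].coords - p.coords)
        return [p.coords + length * unit(-(u1 + u2))]

    if n_h == 2 and len(heavies) == 2:
        # methylene: mirror pair about the heavy-atom plane
        u1 = unit(heavies[0].coords - p.coords)
        u2 = unit(heavies[1].coords - p.coords)
        bisec = unit(-(u1 + u2))
        perp = unit(np.cross(u1, u2))
        half = np.radians(geo["sp3"]) / 2.0
        return [p.coords + length * (np.cos(half) * bisec + s * np.sin(half) * perp)
                for s in (+1.0, -1.0)]

    if n_h == 2 and len(heavies) == 1 and is_sp2:
        # planar NH2 (Asn/Gln amide, Arg NH1/NH2)
        g = _grandparent(model, b, p)
        if g is None:
            return None
        return [place_atom(g.coords, b.coords, p.coords, length, geo["sp2"], phi)
                for phi in (180.0, 0.0)]

    if n_h == 2 and len(heavies) == 1:
        # sp3 NH2/CH2 end group: staggered pair
        g = _grandparent(model, b, p)
        if g is None:
            return None
        theta = geo["sp3"]
        return [place_atom(g.coords, b.coords, p.coords, length, theta, phi)
                for phi in (60.0, 300.0)]

    return None


def place_riding_hydrogens(model: StructureModel, rebuild: bool = False) -> StructureModel:
    """Add hydrogens at ideal geometry (in place; returns the model).

    Deposited hydrogens are kept unless ``rebuild`` is true.  The covalent
    graph is rebuilt afterwards.  Idempotent.
    """
    sites = classify_hydrogen_sites(model)
    for site in sites:
        res = site.residue
        existing = {name for name in site.h_names if res.get_atom(name) is not None}
        if existing == set(site.h_names) and not rebuild:
            continue
        positions = compute_h_positions(model, site)
        if positions is None:
            logger.warning("missing frame atoms for H on %s %s; omitted",
                           res.label, site.parent_atom.name)
            continue
        for name, pos in zip(site.h_names, positions):
            old = res.get_atom(name)
            if old is not None:
                if rebuild:
                    old.coords = np.asarray(pos, dtype=float)
                continue
            res.atoms.append(AtomRecord(
                serial=0, name=name, element="H", coords=pos,
                occupancy=site.parent_atom.occupancy,
                b_factor=site.parent_atom.b_factor,
                altloc=site.parent_atom.altloc,
                is_hydrogen=True,
            ))
    model.reindex()
    build_covalent_graph(model)
    return model
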