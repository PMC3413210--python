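"""Packaged reference tables (residue templates, radii, geometry targets).

All tables are plain JSON and may be overridden by user-supplied files of the
same schema.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def load_table(name: str) -> dict:
    """Load a packaged JSON table by file name (e.g. ``'residues.json'``)."""
    ref = resources.files(__package__).joinpath(name)
    with ref.open("r") as fh:
        return json.load(fh)


def residue_templates() -> dict:
    return load_table("residues.json")


def vdw_tables() -> dict:
    return load_table("vdw_radii.json")


def h_geometry() -> dict:
    return load_table("h_geometry.json")


def geometry_targets_raw() -> dict:
    return load_table("geometry_targets.json")
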