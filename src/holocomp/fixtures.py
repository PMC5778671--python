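"""Shipped illustrative pathway fixtures.

The amino-acid and vitamin pathway files encode, at figure-level
granularity, the characteristic complementation patterns of a sap-feeding
host and its two bacterial endosymbionts: essential amino acids whose
synthesis needs enzymes from both host and primary symbiont (the
host-upstream / symbiont-terminal and symbiont-upstream / host-terminal
patterns), amino acids that host and secondary symbiont can each make alone,
and B vitamins only the secondary symbiont can complete.  They are synthetic
teaching fixtures, not a database extraction.
"""

from __future__ import annotations

import json
from importlib import resources

from .formats_io import PathwayDefinition, read_pathways
from .pathway_complementation import GenomeInventory

__all__ = ["load_amino_acid_fixture", "load_vitamin_fixture", "load_inventories"]


def _data_path(name: str):
    return resources.files("holocomp.data").joinpath(name)


def _load_pathways(name: str) -> list[PathwayDefinition]:
    with resources.as_file(_data_path(name)) as path:
        return read_pathways(path)


def load_inventories() -> list[GenomeInventory]:
    data = json.loads(_data_path("example_inventories.json").read_text())
    return [GenomeInventory(gid, data["roles"][gid], frozenset(ecs))
            for gid, ecs in data["ec_sets"].items()]


def load_amino_acid_fixture() -> tuple[list[PathwayDefinition], list[GenomeInventory]]:
    return _load_pathways("amino_acid_pathways.json"), load_inventories()


def load_vitamin_fixture() -> tuple[list[PathwayDefinition], list[GenomeInventory]]:
    return _load_pathways("vitamin_pathways.json"), load_inventories()
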