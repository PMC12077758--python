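"""Inventory of the compiled Tropical Western Atlantic decapod COI dataset.

One row per species/lineage (cryptic northern/southern lineages are separate
rows) with its taxonomic group, the signed latitudinal range analysed and the
number of COI sequences compiled.  The sequences themselves live in GenBank
and are not shipped; the inventory supports dataset bookkeeping — totals,
species counts, range spans — without downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

def load_study_inventory() -> pd.DataFrame:
    """Species/lineage inventory with per-lineage sequence counts."""
    ref = resources.files("latdiv").joinpath("data/study_inventory.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def total_sequences(inventory: pd.DataFrame | None = None) -> int:
    inv = load_study_inventory() if inventory is None else inventory
    return int(inv["n_sequences"].sum())


def n_lineages(inventory: pd.DataFrame | None = None) -> int:
    inv = load_study_inventory() if inventory is None else inventory
    return int(len(inv))
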