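"""Bundled reference data: the printed cross-species enzyme table.

The nine-species enzyme relative-abundance table (cells are relative
abundances x10^6) ships with the package, together with its enzyme ->
substrate annotation.  Species are abbreviated by genus/species codes;
``SPECIES_DIET`` records each host's feeding group.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

#: Column order of the species in the bundled table.
SPECIES = ("Mn", "Od", "Cu", "Aw", "Nt", "Th", "Co", "Mp", "Nc")

SPECIES_DIET = {
    "Mn": "fungus",
    "Od": "fungus",
    "Cu": "soil",
    "Aw": "dung",
    "Nt": "humus",
    "Th": "humus",
    "Co": "litter",
    "Mp": "wood",
    "Nc": "wood",
}

FUNGUS_FEEDERS = ("Mn", "Od")
WOOD_FEEDERS = ("Mp", "Nc")


def _table1_path():
    return files("metacaz.data") / "table1.tsv"


def load_table1() -> pd.DataFrame:
    """Tidy form of the bundled table: ec, enzyme, substrate + nine species columns."""
    with _table1_path().open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def enzyme_label(ec: str, enzyme: str) -> str:
    """Unique column label for an enzyme row (EC numbers repeat, names do not)."""
    return f"{ec}|{enzyme}"


def table1_matrix() -> pd.DataFrame:
    """Species x enzymes matrix of the bundled table (display-scaled units).

    Rows are the nine species in table order; columns are labelled
    ``"<ec>|<enzyme name>"`` because two partial ECs each appear twice.
    """
    df = load_table1()
    labels = [enzyme_label(e, n) for e, n in zip(df["ec"], df["enzyme"])]
    matrix = df[list(SPECIES)].T
    matrix.columns = labels
    matrix.index.name = "species"
    return matrix.astype(float)


def substrate_map() -> pd.Series:
    """Enzyme label -> substrate class, exactly as annotated in the bundled table."""
    df = load_table1()
    labels = [enzyme_label(e, n) for e, n in zip(df["ec"], df["enzyme"])]
    return pd.Series(df["substrate"].to_numpy(), index=labels, name="substrate")
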