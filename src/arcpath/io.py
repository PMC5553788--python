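"""Readers and writers for the tabular input files and report tables.

Input bundle layout (all plain text):

* ``reactions.keg``  KEGG-flat-file-subset reaction records
* ``pairs.tsv``      reaction_id, substrate_id, product_id, category
* ``thermo.tsv``     reaction_id, drG_m_kJ_mol (blank = missing)
* ``compounds.tsv``  id, name, mass (blank = missing), generic (0/1)
* ``basis.txt`` / ``cofactors.txt`` / ``excluded.txt`` / ``host.txt``
  one metabolite or reaction id per line, ``#`` comments allowed
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "read_pairs_tsv",
    "read_thermo_tsv",
    "read_compounds_tsv",
    "read_id_list",
    "write_id_list",
]


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    need = ["reaction_id", "substrate_id", "product_id", "category"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [tuple(row) for row in df[need].itertuples(index=False)]


def read_thermo_tsv(path: str | Path) -> dict[str, float | None]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "reaction_id" not in df.columns or "drG_m_kJ_mol" not in df.columns:
        raise ValueError(f"{path}: need columns reaction_id, drG_m_kJ_mol")
    out: dict[str, float | None] = {}
    for rid, dg in zip(df["reaction_id"], df["drG_m_kJ_mol"]):
        out[str(rid)] = None if pd.isna(dg) else float(dg)
    return out


def read_compounds_tsv(
    path: str | Path,
) -> tuple[dict[str, float | None], dict[str, str], set[str]]:
    """Returns (masses, names, generic-metabolite ids)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "id" not in df.columns:
        raise ValueError(f"{path}: need an 'id' column")
    masses: dict[str, float | None] = {}
    names: dict[str, str] = {}
    generic: set[str] = set()
    for _, row in df.iterrows():
        mid = str(row["id"])
        mass = row.get("mass")
        masses[mid] = None if mass is None or (
            isinstance(mass, float) and math.isnan(mass)
        ) else float(mass)
        if "name" in df.columns and not pd.isna(row.get("name")):
            names[mid] = str(row["name"])
        if "generic" in df.columns and not pd.isna(row.get("generic")):
            if int(row["generic"]):
                generic.add(mid)
    return masses, names, generic


def read_id_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_id_list(path: str | Path, ids: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))
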