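"""Cross-cohort biomarker presence/absence accounting.

Encodes the published presence table of NMR serum schizophrenia biomarkers
across the Serbian, Brazilian and Chinese cohorts and answers the overlap
arithmetic: how many metabolites are shared by any subset of cohorts, and
which metabolites form the all-cohort consensus set.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

COHORTS = ("Serbian", "Brazilian", "Chinese")

#: source-table spellings -> canonical names
SYNONYMS = {
    "Serin": "Serine",
    "PABA": "4-Aminobenzoic acid",
    "Lactate/lactic acid": "Lactate",
    "Glutamate/glutamic acid": "Glutamate",
    "Citrate/citric acid": "Citrate",
    "Aspartate/aspartic acid": "Aspartate",
    "Methymalonic acid": "Methylmalonic acid",
    "3-methyl-2-oxobutunoic acid": "3-Methyl-2-oxobutanoic acid",
}

_TRUE = {"+", "true", "1", "yes"}
_FALSE = {"−", "-", "false", "0", "no"}


@dataclasses.dataclass
class PresenceMatrix:
    """Metabolite x cohort boolean table with per-row reference tags."""

    table: pd.DataFrame  # boolean, index = metabolite names (row order kept)
    refs: pd.Series
    notes: pd.Series

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate metabolites: {dupes}")
        if not self.table.dtypes.eq(bool).all():
            raise ValueError("presence matrix must be strictly boolean")

    @property
    def cohorts(self) -> list[str]:
        return list(self.table.columns)

    @property
    def metabolites(self) -> list[str]:
        return list(self.table.index)

    def canonical_name(self, metabolite: str) -> str:
        return SYNONYMS.get(metabolite, metabolite)


def load_presence_table(path: str | Path) -> PresenceMatrix:
    """Read a delimited presence table ('+'/'−' grid with a cohort header)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty or "metabolite" not in df.columns:
        raise ValueError("presence table is empty or lacks a metabolite column")
    cohort_cols = [c for c in df.columns if c not in ("metabolite", "refs", "note")]
    if not cohort_cols:
        raise ValueError("presence table has no cohort columns")

    def decode(cell: str) -> bool:
        cell = str(cell).strip()
        if cell in _TRUE:
            return True
        if cell in _FALSE:
            return False
        raise ValueError(f"unknown presence symbol {cell!r}")

    table = df[cohort_cols].map(decode)
    table.index = df["metabolite"]
    refs = df.get("refs", pd.Series("", index=df.index)).fillna("")
    notes = df.get("note", pd.Series("", index=df.index)).fillna("")
    refs.index = notes.index = df["metabolite"]
    return PresenceMatrix(table=table, refs=refs, notes=notes)


def load_default_presence_table() -> PresenceMatrix:
    ref = resources.files("serumnmr.data").joinpath("cohort_presence.tsv")
    with resources.as_file(ref) as path:
        return load_presence_table(path)


def overlap_counts(pm: PresenceMatrix, cohorts) -> int:
    """Number of metabolites present in every named cohort."""
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("cohort subset must be non-empty")
    unknown = [c for c in cohorts if c not in pm.cohorts]
    if unknown:
        raise KeyError(f"unknown cohorts: {unknown}")
    if pm.table.empty:
        return 0
    return int(pm.table[cohorts].all(axis=1).sum())


def consensus_set(pm: PresenceMatrix, cohorts=None) -> list[str]:
    """Metabolites present in all (or the named) cohorts, in row order."""
    cohorts = list(cohorts) if cohorts is not None else pm.cohorts
    mask = pm.table[cohorts].all(axis=1)
    return [m for m, hit in zip(pm.metabolites, mask) if hit]


def overlap_report(pm: PresenceMatrix) -> pd.DataFrame:
    """Counts for each single cohort, pair, and the full intersection."""
    from itertools import combinations

    rows = []
    for r in range(1, len(pm.cohorts) + 1):
        for combo in combinations(pm.cohorts, r):
            rows.append(
                {"cohorts": " ∩ ".join(combo), "count": overlap_counts(pm, combo)}
            )
    return pd.DataFrame(rows)
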