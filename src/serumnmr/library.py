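"""Metabolite multiplet library.

Each metabolite is described by one or more resolved multiplets — chemical
shift, splitting pattern (s, d, t, q, dd, or an unresolved multiplet m),
scalar couplings in Hz and proton count.  The shipped default library covers
the 26 serum metabolites identified as schizophrenia biomarkers in the
Serbian cohort, with shifts and couplings from 2D J-resolved assignments;
it drives both the spectrum simulator and marker-region annotation.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import pandas as pd

PATTERNS = ("s", "d", "t", "q", "dd", "m")
#: patterns whose line positions are governed by scalar couplings
SPLIT_PATTERNS = ("d", "t", "q", "dd")

DEFAULT_FREQUENCY_MHZ = 500.26


@dataclasses.dataclass(frozen=True)
class MultipletSpec:
    """One resolved multiplet of a metabolite."""

    metabolite_name: str
    group_label: str
    center_shift: float  # ppm
    pattern: str
    couplings: tuple[float, ...]  # Hz
    proton_count: int

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not (-1.0 <= self.center_shift <= 12.0):
            raise ValueError(f"center shift {self.center_shift} ppm out of range")
        needs_j = self.pattern in SPLIT_PATTERNS
        if needs_j and not self.couplings:
            raise ValueError(f"pattern {self.pattern!r} requires couplings")
        if not needs_j and self.couplings:
            raise ValueError(f"pattern {self.pattern!r} takes no couplings")
        if self.pattern == "dd" and len(self.couplings) != 2:
            raise ValueError("dd requires exactly two couplings")
        if self.proton_count < 1:
            raise ValueError("proton_count must be >= 1")


@dataclasses.dataclass
class MetaboliteLibrary:
    """Multiplets grouped by metabolite plus the spectrometer frequency."""

    entries: list[MultipletSpec]
    spectrometer_frequency: float = DEFAULT_FREQUENCY_MHZ
    concentrations: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectrometer_frequency <= 0:
            raise ValueError("spectrometer frequency must be positive")
        if not self.entries:
            raise ValueError("library must contain at least one multiplet")

    @property
    def metabolite_names(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.metabolite_name not in seen:
                seen.append(e.metabolite_name)
        return seen

    def __len__(self) -> int:
        return len(self.metabolite_names)

    def multiplets(self, metabolite: str) -> list[MultipletSpec]:
        out = [e for e in self.entries if e.metabolite_name == metabolite]
        if not out:
            raise KeyError(f"no metabolite {metabolite!r} in library")
        return out

    def concentration(self, metabolite: str) -> float:
        return self.concentrations.get(metabolite, 1.0)

    def shifts(self, metabolite: str) -> list[float]:
        return [m.center_shift for m in self.multiplets(metabolite)]


def _parse_couplings(cell: str) -> tuple[float, ...]:
    cell = str(cell).strip()
    if not cell or cell == "nan":
        return ()
    return tuple(float(tok) for tok in cell.split(";"))


def load_library(
    path: str | Path,
    spectrometer_frequency: float = DEFAULT_FREQUENCY_MHZ,
) -> MetaboliteLibrary:
    """Read a multiplet library from its delimited text format.

    Columns: metabolite, group, shift_ppm, pattern, couplings_hz
    (';'-separated, empty for s/m), protons, concentration.  Lines starting
    with '#' are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"metabolite", "group", "shift_ppm", "pattern", "couplings_hz", "protons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library file lacks columns: {sorted(missing)}")
    entries = []
    concentrations: dict[str, float] = {}
    for _, row in df.iterrows():
        entries.append(
            MultipletSpec(
                metabolite_name=row["metabolite"],
                group_label=row["group"],
                center_shift=float(row["shift_ppm"]),
                pattern=row["pattern"],
                couplings=_parse_couplings(row.get("couplings_hz", "")),
                proton_count=int(row["protons"]),
            )
        )
        if "concentration" in df.columns:
            concentrations.setdefault(row["metabolite"], float(row["concentration"]))
    return MetaboliteLibrary(
        entries=entries,
        spectrometer_frequency=spectrometer_frequency,
        concentrations=concentrations,
    )


def load_default_library() -> MetaboliteLibrary:
    """The shipped 26-metabolite serum library at 500.26 MHz."""
    ref = resources.files("serumnmr.data").joinpath("metabolite_library.tsv")
    with resources.as_file(ref) as path:
        return load_library(path)
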