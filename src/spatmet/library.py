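"""Metabolite reference libraries for neutral-mass matching.

A library is a mass-sorted list of records, typically user-supplied
MS1-level annotations from complementary LC-MS/MS runs on the same
sample type.  Records carry a neutral monoisotopic mass and, when
available, a molecular formula (needed for isotope-pattern scoring and
adduct feasibility checks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import ElementCounts, formula_monoisotopic_mass, parse_formula


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str
    neutral_monoisotopic_mass: float
    formula: ElementCounts | None = None
    class_label: str | None = None
    identification_level: str | None = None

    def __post_init__(self):
        if self.neutral_monoisotopic_mass <= 0:
            raise LibraryError(f"{self.id}: neutral mass must be > 0")
        if self.formula:
            derived = formula_monoisotopic_mass(self.formula)
            ppm = abs(derived - self.neutral_monoisotopic_mass) / derived * 1e6
            if ppm > 5:
                warnings.warn(
                    f"record {self.id}: stated mass {self.neutral_monoisotopic_mass:.4f} "
                    f"deviates {ppm:.1f} ppm from formula-derived {derived:.4f}"
                )


@dataclass
class MetaboliteLibrary:
    records: list[MetaboliteRecord]
    provenance: str = "user"
    _masses: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: r.neutral_monoisotopic_mass)
        self._masses = np.array([r.neutral_monoisotopic_mass for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def search_mass(self, mass: float, ppm: float) -> list[MetaboliteRecord]:
        """All records within ``ppm`` of ``mass`` (binary search on sorted masses)."""
        tol = mass * ppm * 1e-6
        lo = np.searchsorted(self._masses, mass - tol, side="left")
        hi = np.searchsorted(self._masses, mass + tol, side="right")
        return self.records[lo:hi]


_COLUMN_ALIASES = {
    "id": ("id", "compound_id", "accession"),
    "name": ("name", "compound", "compound_name", "metabolite"),
    "formula": ("formula", "molecular_formula", "chemical_formula"),
    "mass": ("mass", "neutral_mass", "monoisotopic_mass", "exact_mass", "mono_mass"),
    "class": ("class", "class_label", "category", "super_class"),
    "level": ("level", "identification_level", "msi_level"),
}


def _resolve_columns(columns, column_map):
    resolved = dict(column_map or {})
    lower = {str(c).strip().lower(): c for c in columns}
    for role, aliases in _COLUMN_ALIASES.items():
        if role in resolved:
            continue
        for a in aliases:
            if a in lower:
                resolved[role] = lower[a]
                break
    return resolved


def read_metabolite_library(path, column_map: dict | None = None,
                            delimiter: str | None = None) -> MetaboliteLibrary:
    """Read a delimited metabolite library.

    ``column_map`` maps roles {id, name, formula, mass, class, level} to
    column names; common header names are auto-detected.  At least a mass
    or a formula column is required; records lacking a stated mass get
    the formula-derived monoisotopic mass.  A stated mass disagreeing
    with the formula by > 5 ppm is kept (with a warning) on the grounds
    that the user's stated mass is authoritative.
    """
    from .matrix import _sniff_delimiter

    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if len(df) == 0:
        raise LibraryError(f"{path}: empty library file")
    cols = _resolve_columns(df.columns, column_map)
    if "mass" not in cols and "formula" not in cols:
        raise LibraryError(
            f"{path}: need a mass column or a formula column; found {list(df.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        formula = None
        if "formula" in cols and isinstance(row[cols["formula"]], str):
            formula = parse_formula(row[cols["formula"]])
        mass = None
        if "mass" in cols and pd.notna(row[cols["mass"]]):
            mass = float(row[cols["mass"]])
        if mass is None:
            if formula is None:
                raise LibraryError(f"{path} row {i}: neither mass nor formula present")
            mass = formula_monoisotopic_mass(formula)
        records.append(
            MetaboliteRecord(
                id=str(row[cols["id"]]) if "id" in cols else f"rec{i}",
                name=str(row[cols["name"]]) if "name" in cols else f"rec{i}",
                neutral_monoisotopic_mass=mass,
                formula=formula,
                class_label=str(row[cols["class"]]) if "class" in cols and pd.notna(row[cols["class"]]) else None,
                identification_level=str(row[cols["level"]]) if "level" in cols and pd.notna(row[cols["level"]]) else None,
            )
        )
    return MetaboliteLibrary(records, provenance="user")
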