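"""Adduct definitions, neutral-mass conversion and feasibility checks.

An adduct describes how a neutral molecule M appears as a charged ion:
atoms gained and lost, the charge, and the resulting m/z shift.  The
mass shift accounts for the electron(s) removed, so ``[M+H]+`` shifts by
1.007276 Da (proton mass), not 1.007825 Da (hydrogen atom mass) — at
10 ppm matching in the m/z 100-1000 range the ~0.5 mDa electron mass
matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .elements import ELECTRON_MASS, ElementCounts, formula_monoisotopic_mass, merge_counts


class AdductError(ValueError):
    pass


@dataclass(frozen=True)
class AdductDefinition:
    """A named adduct form, e.g. ``[M+H]+``.

    ``gained``/``lost`` are the literal atom sets added to / removed from
    the neutral molecule.  ``mass_shift`` is derived from them unless
    supplied, and a supplied value must agree with the element arithmetic
    to within 1e-4 Da.
    """

    name: str
    gained: Mapping[str, int] = field(default_factory=dict)
    lost: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1
    mass_shift: float | None = None

    def __post_init__(self):
        if self.charge < 1:
            raise AdductError(f"{self.name}: charge must be >= 1")
        derived = (
            formula_monoisotopic_mass(self.gained)
            - formula_monoisotopic_mass(self.lost)
            - self.charge * ELECTRON_MASS
        )
        if self.mass_shift is None:
            object.__setattr__(self, "mass_shift", derived)
        elif abs(self.mass_shift - derived) > 1e-4:
            raise AdductError(
                f"{self.name}: stated mass_shift {self.mass_shift} inconsistent "
                f"with element delta (expected {derived:.6f})"
            )

    @property
    def element_delta(self) -> ElementCounts:
        """Net atoms gained minus lost (signed)."""
        return merge_counts(self.gained, self.lost, sign=-1)


#: Common positive-mode adducts for small-molecule imaging.
BUILTIN_ADDUCTS: dict[str, AdductDefinition] = {
    a.name: a
    for a in [
        AdductDefinition("[M+H]+", gained={"H": 1}),
        AdductDefinition("[M+Na]+", gained={"Na": 1}),
        AdductDefinition("[M+K]+", gained={"K": 1}),
        AdductDefinition("[M+NH4]+", gained={"N": 1, "H": 4}),
        AdductDefinition("[M+H-H2O]+", gained={"H": 1}, lost={"H": 2, "O": 1}),
    ]
}

DEFAULT_ADDUCT_NAMES: Sequence[str] = tuple(BUILTIN_ADDUCTS)


def get_adducts(names: Sequence[str] | None = None) -> list[AdductDefinition]:
    names = list(names) if names is not None else list(DEFAULT_ADDUCT_NAMES)
    out = []
    for n in names:
        if n not in BUILTIN_ADDUCTS:
            raise AdductError(f"unknown adduct {n!r}; known: {sorted(BUILTIN_ADDUCTS)}")
        out.append(BUILTIN_ADDUCTS[n])
    return out


def neutral_mass(mz: float, adduct: AdductDefinition) -> float:
    """Neutral monoisotopic mass implied by an observed m/z under an adduct."""
    m = mz * adduct.charge - adduct.mass_shift
    if m <= 0:
        raise AdductError(
            f"m/z {mz} under {adduct.name} implies non-positive neutral mass {m:.4f}"
        )
    return m


def mz_from_neutral(mass: float, adduct: AdductDefinition) -> float:
    """Inverse of :func:`neutral_mass`."""
    return (mass + adduct.mass_shift) / adduct.charge


def adduct_feasible(formula: Mapping[str, int], adduct: AdductDefinition) -> bool:
    """Can this molecule form this adduct?

    True iff every atom the adduct removes is available, counting atoms the
    adduct itself adds first.  A molecule without oxygen, such as C7H3F5,
    cannot lose water and is infeasible under ``[M+H-H2O]+``.
    """
    for el, n in adduct.lost.items():
        available = formula.get(el, 0) + adduct.gained.get(el, 0)
        if available < n:
            return False
    return True


def read_adduct_csv(path) -> list[AdductDefinition]:
    """Load user adducts from CSV (name, gained, lost, charge[, mass_shift]).

    ``gained``/``lost`` are formula strings (empty allowed); ``mass_shift``
    is optional and validated against the element arithmetic.
    """
    import pandas as pd

    from .elements import parse_formula

    df = pd.read_csv(path)
    req = {"name", "charge"}
    if not req.issubset(df.columns):
        raise AdductError(f"adduct file needs columns {sorted(req)}")
    out = []
    for _, row in df.iterrows():
        gained = parse_formula(row["gained"]) if _present(row.get("gained")) else {}
        lost = parse_formula(row["lost"]) if _present(row.get("lost")) else {}
        shift = float(row["mass_shift"]) if _present(row.get("mass_shift")) else None
        out.append(
            AdductDefinition(
                str(row["name"]), gained=gained, lost=lost,
                charge=int(row["charge"]), mass_shift=shift,
            )
        )
    return out


def _present(v) -> bool:
    import pandas as pd

    return v is not None and not (isinstance(v, float) and pd.isna(v)) and str(v).strip() != ""
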