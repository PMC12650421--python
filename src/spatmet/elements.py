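"""Element and isotope data plus molecular-formula arithmetic.

The package vendors a fixed isotope mass/abundance table (CODATA/NIST
2021 atomic masses, representative terrestrial abundances) so that mass
calculations and theoretical isotope patterns are reproducible offline
and independent of any external chemistry library version.

A molecular formula is represented as a plain ``dict`` mapping element
symbol to an integer count (``ElementCounts``).  Signed counts are
permitted in intermediate arithmetic (adduct gains/losses); a physical
formula must be non-negative.
"""

from __future__ import annotations

import re
from typing import Dict, Mapping

ElementCounts = Dict[str, int]

#: CODATA/NIST isotope masses (Da) and isotopic abundances, per element.
#: Each entry is a list of (exact mass, abundance) sorted by mass.
ISOTOPES: Dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "B": [(10.0129369, 0.199), (11.0093052, 0.801)],
    "C": [(12.0, 0.9893), (13.0033548352, 0.0107)],
    "N": [(14.0030740044, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.9949146196, 0.99757), (16.9991317565, 0.00038), (17.9991596129, 0.00205)],
    "F": [(18.9984031627, 1.0)],
    "Na": [(22.9897692820, 1.0)],
    "Mg": [(23.9850416970, 0.7899), (24.9858369760, 0.1000), (25.9825929680, 0.1101)],
    "Si": [(27.9769265347, 0.92223), (28.9764946649, 0.04685), (29.9737701360, 0.03092)],
    "P": [(30.9737619984, 1.0)],
    "S": [(31.9720711744, 0.9499), (32.9714589098, 0.0075),
          (33.9678670040, 0.0425), (35.9670807100, 0.0001)],
    "Cl": [(34.9688526820, 0.7576), (36.9659026030, 0.2424)],
    "K": [(38.9637064864, 0.932581), (39.9639981660, 0.000117), (40.9618252579, 0.067302)],
    "Ca": [(39.9625908630, 0.96941), (41.9586178310, 0.00647), (42.9587664300, 0.00135),
           (43.9554815610, 0.02086), (45.9536890000, 0.00004), (47.9525227650, 0.00187)],
    "Fe": [(53.9396083060, 0.05845), (55.9349363260, 0.91754),
           (56.9353928410, 0.02119), (57.9332744310, 0.00282)],
    "Zn": [(63.9291420100, 0.4917), (65.9260338100, 0.2773), (66.9271277500, 0.0404),
           (67.9248445500, 0.1845), (69.9253192000, 0.0061)],
    "Se": [(73.9224759340, 0.0089), (75.9192137040, 0.0937), (76.9199141540, 0.0763),
           (77.9173092800, 0.2377), (79.9165218000, 0.4961), (81.9166994970, 0.0873)],
    "Br": [(78.9183376010, 0.5069), (80.9162897860, 0.4931)],
    "I": [(126.9044718530, 1.0)],
}

#: Exact mass of the principal (most abundant) isotope per element.
#: For the elements of organic chemistry (CHNOPS, halogens) the principal
#: isotope is also the lightest, so this is the conventional monoisotopic
#: mass used throughout mass spectrometry.
PRINCIPAL_MASS: Dict[str, float] = {
    el: max(isos, key=lambda mi: mi[1])[0] for el, isos in ISOTOPES.items()
}

#: Electron rest mass in Da; adduct m/z arithmetic is electron-mass aware.
ELECTRON_MASS = 0.000548579909


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(s: str) -> ElementCounts:
    """Parse a Hill-style molecular formula into element counts.

    ``"C7H3F5"`` -> ``{"C": 7, "H": 3, "F": 5}``.  An omitted count means
    one atom.  Repeated element symbols are summed.  Only elements present
    in the bundled isotope table are accepted.
    """
    if not isinstance(s, str) or not s.strip():
        raise FormulaError(f"empty or non-string formula: {s!r}")
    s = s.strip()
    counts: ElementCounts = {}
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {s!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ISOTOPES:
            raise FormulaError(f"unknown element symbol {el!r} in formula {s!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(s):
        raise FormulaError(f"malformed formula {s!r} at position {pos}")
    return counts


def formula_monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x principal-isotope mass.

    Accepts signed counts (used for adduct deltas); an empty formula has
    mass 0.
    """
    try:
        return sum(n * PRINCIPAL_MASS[el] for el, n in f.items())
    except KeyError as e:
        raise FormulaError(f"unknown element symbol {e.args[0]!r}") from None


def formula_to_string(f: Mapping[str, int]) -> str:
    """Render counts in Hill order (C, H, then alphabetical)."""
    parts = []
    rest = sorted(el for el in f if el not in ("C", "H"))
    for el in ["C", "H"] + rest:
        n = f.get(el, 0)
        if n == 0:
            continue
        parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def merge_counts(a: Mapping[str, int], b: Mapping[str, int], sign: int = 1) -> ElementCounts:
    """Return a + sign*b as element counts (zero entries dropped)."""
    out: ElementCounts = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
        if out[el] == 0:
            del out[el]
    return out
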