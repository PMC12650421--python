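"""Theoretical isotope patterns and spectral-entropy similarity.

The fine-structure isotopologue pattern of a formula is built by
iterative convolution: each element's isotope distribution is raised to
the power of its atom count (by repeated squaring), and the per-element
distributions are convolved together.  After every convolution, peaks
closer than a merge tolerance are combined (abundance-weighted mass) and
peaks below a relative-abundance floor are pruned, which keeps the peak
list small for large formulas while remaining exact for small ones.

Pattern-versus-observation agreement is scored with spectral-entropy
similarity: with both spectra normalized to unit total intensity and
Shannon entropies S_a, S_b and S_ab of the half-and-half merged
spectrum,

    similarity = 1 - (2 * S_ab - S_a - S_b) / ln(4)

which is 1 for identical spectra and 0 for disjoint ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .adducts import AdductDefinition
from .elements import ELECTRON_MASS, ISOTOPES, FormulaError, merge_counts


@dataclass
class TheoreticalPattern:
    masses: np.ndarray       # strictly increasing, m/z units if an adduct applied
    abundances: np.ndarray   # normalized so max == 1, all in (0, 1]
    prune: float

    def as_peaks(self) -> np.ndarray:
        return np.column_stack([self.masses, self.abundances])


def _merge_peaks(masses: np.ndarray, abund: np.ndarray, tol: float):
    """Combine peaks within ``tol`` Da (abundance-weighted mass)."""
    order = np.argsort(masses)
    masses, abund = masses[order], abund[order]
    out_m, out_a = [], []
    cur_m, cur_a = masses[0] * abund[0], abund[0]
    cur_ref = masses[0]
    for m, a in zip(masses[1:], abund[1:]):
        if m - cur_ref <= tol:
            cur_m += m * a
            cur_a += a
        else:
            out_m.append(cur_m / cur_a)
            out_a.append(cur_a)
            cur_m, cur_a = m * a, a
        cur_ref = m
    out_m.append(cur_m / cur_a)
    out_a.append(cur_a)
    return np.array(out_m), np.array(out_a)


def _convolve(pa, pb, prune: float, merge_tol: float):
    ma, aa = pa
    mb, ab = pb
    m = (ma[:, None] + mb[None, :]).ravel()
    a = (aa[:, None] * ab[None, :]).ravel()
    m, a = _merge_peaks(m, a, merge_tol)
    keep = a >= prune * a.max()
    return m[keep], a[keep]


def _element_power(el: str, n: int, prune: float, merge_tol: float):
    isos = ISOTOPES[el]
    base = (np.array([m for m, _ in isos]), np.array([p for _, p in isos]))
    result = (np.zeros(1), np.ones(1))
    # binary exponentiation keeps the intermediate peak lists short
    while n > 0:
        if n & 1:
            result = _convolve(result, base, prune, merge_tol)
        n >>= 1
        if n:
            base = _convolve(base, base, prune, merge_tol)
    return result


def theoretical_isotope_pattern(
    formula: Mapping[str, int],
    adduct: AdductDefinition | None = None,
    prune: float = 1e-3,
    merge_tol: float = 1e-4,
) -> TheoreticalPattern:
    """Fine-structure isotopologue pattern of a (possibly adduct-modified) formula.

    If an adduct is given, its gained/lost atoms are applied to the
    formula and the resulting pattern is expressed in m/z units
    (electron mass removed, divided by charge).  Abundances are
    normalized to a maximum of 1; ``prune`` is the relative-abundance
    floor applied after each convolution step.
    """
    comp = dict(formula)
    charge = 0
    if adduct is not None:
        comp = merge_counts(merge_counts(comp, adduct.gained), adduct.lost, sign=-1)
        if any(n < 0 for n in comp.values()):
            raise FormulaError(
                f"adduct {adduct.name} removes atoms the formula lacks: {comp}"
            )
        charge = adduct.charge
    unknown = [el for el in comp if el not in ISOTOPES]
    if unknown:
        raise FormulaError(f"unknown element(s) {unknown}")
    masses, abund = np.zeros(1), np.ones(1)
    for el, n in sorted(comp.items()):
        if n == 0:
            continue
        masses, abund = _convolve(
            (masses, abund), _element_power(el, n, prune, merge_tol), prune, merge_tol
        )
    if charge:
        masses = (masses - charge * ELECTRON_MASS) / charge
    abund = abund / abund.max()
    keep = abund >= prune
    return TheoreticalPattern(masses[keep], abund[keep], prune)


# ------------------------------------------------- entropy similarity


def _normalize_spectrum(spec) -> tuple[np.ndarray, np.ndarray]:
    peaks = np.asarray(spec, dtype=float)
    if peaks.ndim != 2 or peaks.shape[1] != 2 or len(peaks) == 0:
        raise ValueError("spectrum must be a non-empty (n, 2) array of (mass, intensity)")
    if np.any(peaks[:, 1] < 0) or peaks[:, 1].sum() <= 0:
        raise ValueError("spectrum intensities must be non-negative with positive sum")
    order = np.argsort(peaks[:, 0])
    m = peaks[order, 0]
    i = peaks[order, 1] / peaks[:, 1].sum()
    return m, i


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy_similarity(spec_a, spec_b, match_tol: float = 0.01,
                       ppm: float | None = None) -> float:
    """Spectral-entropy similarity in [0, 1] between two peak lists.

    ``spec_a``/``spec_b`` are (n, 2) arrays of (mass, intensity).  Peaks
    are matched within ``match_tol`` Da, or within ``ppm`` of the peak
    mass when given.  The score is invariant to rescaling either
    spectrum's intensities and symmetric in its arguments.
    """
    ma, ia = _normalize_spectrum(spec_a)
    mb, ib = _normalize_spectrum(spec_b)
    # pool both spectra at half weight, then cluster peaks within tolerance
    masses = np.concatenate([ma, mb])
    weights = np.concatenate([ia, ib]) / 2.0
    order = np.argsort(masses)
    masses, weights = masses[order], weights[order]
    merged = []
    cur = weights[0]
    for k in range(1, len(masses)):
        tol = masses[k] * ppm * 1e-6 if ppm is not None else match_tol
        if masses[k] - masses[k - 1] <= tol:
            cur += weights[k]
        else:
            merged.append(cur)
            cur = weights[k]
    merged.append(cur)
    s_ab = _shannon(np.array(merged))
    s_a = _shannon(ia)
    s_b = _shannon(ib)
    sim = 1.0 - (2.0 * s_ab - s_a - s_b) / np.log(4.0)
    return float(np.clip(sim, 0.0, 1.0))
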