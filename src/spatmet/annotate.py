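"""Isotope/adduct relationship detection and multi-evidence annotation.

The annotation workflow runs on a noise-filtered tissue matrix:

1. Isotope pairs: peak pairs separated by the +1 isotopologue spacing
   (13C - 12C = 1.003355 Da for singly charged ions) within the ppm
   tolerance, whose mean intensity ratio is chemically plausible and
   whose spatial distributions agree (bivariate Moran's I >= rho).
   Chains (+2, +3, ...) are grown from confirmed +1 peaks.  Confirmed
   non-monoisotopic peaks are removed before adduct detection.
2. Adduct pairs: ion pairs whose neutral masses under a pair of adduct
   hypotheses coincide within tolerance, confirmed by the same spatial
   criterion.
3. Database matching: ions with a confirmed adduct form are matched by
   that single neutral mass; other ions try every adduct in the user
   list.  Chemically impossible combinations (the matched formula lacks
   the atoms an adduct loss removes) are discarded.  Ions with a
   confirmed isotope chain additionally get an isotope-pattern entropy
   similarity against the matched formula's theoretical pattern.
4. Composite score: a weighted sum of mass accuracy, isotope similarity
   and adduct evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adducts import AdductDefinition, adduct_feasible, neutral_mass
from .elements import formula_to_string
from .isotopes import entropy_similarity, theoretical_isotope_pattern
from .library import MetaboliteLibrary, MetaboliteRecord
from .matrix import FeatureMatrix
from .params import AnalysisParams
from .spatial import (SpatialWeights, bivariate_moran_pairs, build_spatial_weights,
                      moran_matrix_prepare)

log = logging.getLogger(__name__)

#: 13C - 12C mass difference in Da.
C13_DELTA = 1.0033548352


@dataclass(frozen=True)
class IsotopePair:
    mono_ion: int          # index of the chain's monoisotopic ion
    iso_ion: int
    label: str             # "+1 (13C)", "+2 (13C)", ...
    delta_mz: float
    ppm_error: float
    moran_i: float
    intensity_ratio: float  # mean(iso) / mean(previous peak in chain)


@dataclass(frozen=True)
class AdductPair:
    ion_a: int
    ion_b: int
    adduct_a: str
    adduct_b: str
    neutral_mass: float
    ppm_error: float
    moran_i: float


@dataclass
class AnnotationCandidate:
    ion: int
    mz: float
    record: MetaboliteRecord
    adduct: str
    adduct_evidence: bool      # pair-confirmed vs merely hypothesized
    ppm_error: float
    isotope_similarity: float | None = None
    conflicting: bool = False
    score: float = float("nan")
    rank: int = 0


@dataclass
class AnnotationSummary:
    total_ions: int
    n_annotated: int
    fraction_annotated: float
    histogram: dict            # {"1": n1, "2": n2, "3+": n3}
    multi_match_mz: list       # m/z of ions with >= 2 candidates


# ---------------------------------------------------- isotope pairs


def _plausible_ratio_bound(mz: float) -> float:
    """Max credible +1/mono intensity ratio: 1.1% per carbon, at most mz/12 carbons."""
    return 0.011 * np.floor(mz / 12.0)


def find_isotope_pairs(
    fm: FeatureMatrix,
    params: AnalysisParams | None = None,
    weights: SpatialWeights | None = None,
    charge: int = 1,
) -> list[IsotopePair]:
    """Detect isotopologue chains among the ions of a (filtered) matrix.

    A +1 candidate must match the isotope spacing within the ppm
    tolerance, have mean intensity at most the carbon-count plausibility
    bound times its parent's, and show Moran's I at or above the spatial
    correlation threshold.  An ion claimed by several parents keeps the
    assignment with the highest I.
    """
    params = params or AnalysisParams()
    weights = weights or build_spatial_weights(fm.coords)
    rho = params.spatial_correlation_threshold
    spacing = C13_DELTA / charge
    means = fm.intensities.mean(axis=0)
    Z, WZ, ss = moran_matrix_prepare(fm.intensities, weights)

    def plus_one_candidates(parents: np.ndarray) -> list[tuple[int, int, float]]:
        """(parent, child, ppm) candidates passing mass and ratio gates."""
        out = []
        for i in parents:
            target = fm.mz[i] + spacing
            tol = fm.mz[i] * params.ppm_tolerance * 1e-6
            for j in fm.ions_near(target, tol):
                if j == i or means[i] <= 0:
                    continue
                ratio = means[j] / means[i]
                if ratio > _plausible_ratio_bound(fm.mz[i]):
                    continue
                ppm = (fm.mz[j] - target) / fm.mz[i] * 1e6
                out.append((int(i), int(j), float(ppm)))
        return out

    confirmed: dict[int, tuple[int, float, float]] = {}  # child -> (parent, I, ppm)

    def confirm(cands):
        if not cands:
            return []
        arr = np.array([(a, b) for a, b, _ in cands], dtype=int)
        morans = bivariate_moran_pairs(arr, Z, WZ, ss, weights)
        newly = []
        for (a, b, ppm), i_val in zip(cands, morans):
            if not np.isfinite(i_val) or i_val < rho:
                continue
            if b in confirmed and confirmed[b][1] >= i_val:
                continue
            confirmed[b] = (a, float(i_val), ppm)
            newly.append(b)
        return newly

    roots = np.arange(fm.n_ions)
    new_children = confirm(plus_one_candidates(roots))
    # grow chains from confirmed isotopic peaks
    while new_children:
        new_children = confirm(plus_one_candidates(np.array(sorted(new_children))))

    # a confirmed isotopic peak cannot head its own chain: walk to the root
    def chain_root(ion: int) -> int:
        seen = set()
        while ion in confirmed and ion not in seen:
            seen.add(ion)
            ion = confirmed[ion][0]
        return ion

    pairs = []
    for child, (parent, i_val, ppm) in sorted(confirmed.items()):
        root = chain_root(parent)
        k = int(round((fm.mz[child] - fm.mz[root]) / spacing))
        pairs.append(
            IsotopePair(
                mono_ion=int(root),
                iso_ion=int(child),
                label=f"+{k} (13C)",
                delta_mz=float(fm.mz[child] - fm.mz[parent]),
                ppm_error=ppm,
                moran_i=i_val,
                intensity_ratio=float(means[child] / means[parent]) if means[parent] > 0 else np.nan,
            )
        )
    log.info("isotope detection: %d isotopic peaks among %d ions", len(pairs), fm.n_ions)
    return pairs


def ion_roles(fm: FeatureMatrix, pairs: list[IsotopePair]) -> np.ndarray:
    """Per-ion role: 'monoisotopic' (heads a chain), 'isotopic', or 'unpaired'."""
    roles = np.array(["unpaired"] * fm.n_ions, dtype=object)
    for p in pairs:
        roles[p.mono_ion] = "monoisotopic"
        roles[p.iso_ion] = "isotopic"
    return roles


def remove_isotopic_peaks(fm: FeatureMatrix, pairs: list[IsotopePair]) -> FeatureMatrix:
    """Drop ions confirmed as non-monoisotopic peaks (idempotent)."""
    iso = {p.iso_ion for p in pairs if p.iso_ion < fm.n_ions}
    if not iso:
        return fm
    log.info("removing %d isotopic peaks", len(iso))
    return fm.drop_ions(iso)


# ----------------------------------------------------- adduct pairs


def find_adduct_pairs(
    fm: FeatureMatrix,
    adducts: list[AdductDefinition],
    params: AnalysisParams | None = None,
    weights: SpatialWeights | None = None,
) -> list[AdductPair]:
    """Detect ion pairs explainable as two adduct forms of one neutral mass.

    For every unordered ion pair (i, j) with mz_i < mz_j and every
    adduct hypothesis pair (A, B) with shift_A < shift_B, the pair is a
    candidate when the implied neutral masses agree within the ppm
    tolerance; candidates are confirmed at Moran's I >= rho (default 0.5).
    Expects isotopic peaks to have been removed.
    """
    params = params or AnalysisParams()
    weights = weights or build_spatial_weights(fm.coords)
    rho = params.spatial_correlation_threshold
    Z, WZ, ss = moran_matrix_prepare(fm.intensities, weights)

    cands: list[tuple[int, int, AdductDefinition, AdductDefinition, float, float]] = []
    for a in adducts:
        for b in adducts:
            if not (a.mass_shift < b.mass_shift and a.charge == b.charge == 1):
                continue
            # mz_i - shift_a == mz_j - shift_b  =>  mz_j = mz_i + (shift_b - shift_a)
            delta = b.mass_shift - a.mass_shift
            for i in range(fm.n_ions):
                m_i = fm.mz[i] - a.mass_shift
                if m_i <= 0:
                    continue
                tol = m_i * params.ppm_tolerance * 1e-6
                for j in fm.ions_near(fm.mz[i] + delta, tol):
                    if j <= i:
                        continue
                    m_j = fm.mz[j] - b.mass_shift
                    ppm = (m_j - m_i) / m_i * 1e6
                    cands.append((i, int(j), a, b, 0.5 * (m_i + m_j), float(ppm)))

    if not cands:
        return []
    arr = np.array([(c[0], c[1]) for c in cands], dtype=int)
    morans = bivariate_moran_pairs(arr, Z, WZ, ss, weights)
    out = []
    for (i, j, a, b, m, ppm), i_val in zip(cands, morans):
        if np.isfinite(i_val) and i_val >= rho:
            out.append(AdductPair(i, j, a.name, b.name, m, ppm, float(i_val)))
    log.info("adduct detection: %d confirmed pairs from %d candidates", len(out), len(cands))
    return out


# -------------------------------------------------- database matching


def _confirmed_hypotheses(n_ions: int, adduct_pairs: list[AdductPair]) -> dict[int, list[tuple[str, float]]]:
    hyp: dict[int, list[tuple[str, float]]] = {}
    for p in adduct_pairs:
        hyp.setdefault(p.ion_a, []).append((p.adduct_a, p.neutral_mass))
        hyp.setdefault(p.ion_b, []).append((p.adduct_b, p.neutral_mass))
    return hyp


def match_database(
    fm: FeatureMatrix,
    isotope_pairs: list[IsotopePair],
    adduct_pairs: list[AdductPair],
    library: MetaboliteLibrary,
    adduct_list: list[AdductDefinition],
    params: AnalysisParams | None = None,
    tissue_means: np.ndarray | None = None,
) -> list[AnnotationCandidate]:
    """Match each (monoisotopic) ion's neutral mass against the library.

    ``fm`` must be the matrix the isotope/adduct detection indices refer
    to (isotopic peaks may still be present; they are skipped here).
    All matches are retained for user reference; chemically infeasible
    formula/adduct combinations are dropped.  Ions that are members of
    several confirmed adduct pairs with disagreeing neutral masses keep
    all interpretations, flagged ``conflicting``.
    """
    params = params or AnalysisParams()
    if len(library) == 0:
        raise ValueError("empty metabolite library")
    by_name = {a.name: a for a in adduct_list}
    hyp = _confirmed_hypotheses(fm.n_ions, adduct_pairs)
    roles = ion_roles(fm, isotope_pairs)
    means = tissue_means if tissue_means is not None else fm.intensities.mean(axis=0)

    # observed isotopologue chain spectrum per chain root
    chains: dict[int, list[IsotopePair]] = {}
    for p in isotope_pairs:
        chains.setdefault(p.mono_ion, []).append(p)

    out: list[AnnotationCandidate] = []
    for ion in range(fm.n_ions):
        if roles[ion] == "isotopic":
            continue
        if ion in hyp:
            masses = {}
            for name, m in hyp[ion]:
                masses.setdefault(name, []).append(m)
            uniq = [(name, float(np.mean(v))) for name, v in masses.items()]
            all_m = [m for _, v in masses.items() for m in v]
            conflicting = (max(all_m) - min(all_m)) / min(all_m) * 1e6 > params.ppm_tolerance
            hypotheses = [(name, m, True, conflicting) for name, m in uniq]
        else:
            hypotheses = []
            for a in adduct_list:
                m = fm.mz[ion] * a.charge - a.mass_shift
                if m > 0:
                    hypotheses.append((a.name, m, False, False))
        for adduct_name, m, evidence, conflicting in hypotheses:
            adduct = by_name.get(adduct_name)
            for rec in library.search_mass(m, params.ppm_tolerance):
                if rec.formula is not None and adduct is not None:
                    if not adduct_feasible(rec.formula, adduct):
                        continue
                ppm = (m - rec.neutral_monoisotopic_mass) / rec.neutral_monoisotopic_mass * 1e6
                iso_sim = None
                if ion in chains and rec.formula is not None and adduct is not None:
                    iso_sim = _isotope_similarity(
                        fm, ion, chains[ion], rec, adduct, means, params
                    )
                out.append(
                    AnnotationCandidate(
                        ion=ion, mz=float(fm.mz[ion]), record=rec,
                        adduct=adduct_name, adduct_evidence=evidence,
                        ppm_error=float(ppm), isotope_similarity=iso_sim,
                        conflicting=conflicting,
                    )
                )
    return out


def _isotope_similarity(fm, ion, chain, rec, adduct, means, params) -> float | None:
    """Entropy similarity of theoretical vs observed isotopologue pattern."""
    obs_peaks = [(fm.mz[ion], means[ion])]
    for p in sorted(chain, key=lambda p: fm.mz[p.iso_ion]):
        obs_peaks.append((fm.mz[p.iso_ion], means[p.iso_ion]))
    obs = np.array(obs_peaks)
    if obs[:, 1].sum() <= 0:
        return None
    try:
        theo = theoretical_isotope_pattern(rec.formula, adduct, prune=params.isotope_prune)
    except Exception:
        return None
    return entropy_similarity(theo.as_peaks(), obs, match_tol=params.pattern_match_tol)


# ------------------------------------------------------- scoring


def score_annotations(
    candidates: list[AnnotationCandidate],
    params: AnalysisParams | None = None,
) -> list[AnnotationCandidate]:
    """Composite score: w_mass * (1 - |ppm|/tol) + w_iso * iso_sim + w_add * 1{evidence}.

    When an ion has no isotope similarity the isotope weight is
    redistributed proportionally onto the other two terms, so the score
    stays on the [0, 1] scale.  Candidates are ranked per ion by score
    (descending), ties broken by |ppm|.
    """
    params = params or AnalysisParams()
    w_mass, w_iso, w_add = params.score_weights
    tol = params.ppm_tolerance
    for c in candidates:
        mass_term = max(0.0, 1.0 - abs(c.ppm_error) / tol)
        add_term = 1.0 if c.adduct_evidence else 0.0
        if c.isotope_similarity is None:
            rest = w_mass + w_add
            if rest == 0:
                c.score = 0.0
            else:
                c.score = (w_mass * mass_term + w_add * add_term) / rest
        else:
            c.score = w_mass * mass_term + w_iso * c.isotope_similarity + w_add * add_term
    by_ion: dict[int, list[AnnotationCandidate]] = {}
    for c in candidates:
        by_ion.setdefault(c.ion, []).append(c)
    for ion, group in by_ion.items():
        group.sort(key=lambda c: (-c.score, abs(c.ppm_error)))
        for r, c in enumerate(group, start=1):
            c.rank = r
    return candidates


def annotation_summary(candidates: list[AnnotationCandidate], total_ions: int) -> AnnotationSummary:
    per_ion: dict[int, int] = {}
    mz_of: dict[int, float] = {}
    for c in candidates:
        per_ion[c.ion] = per_ion.get(c.ion, 0) + 1
        mz_of[c.ion] = c.mz
    hist = {"1": 0, "2": 0, "3+": 0}
    for n in per_ion.values():
        hist["1" if n == 1 else "2" if n == 2 else "3+"] += 1
    n_annot = len(per_ion)
    return AnnotationSummary(
        total_ions=total_ions,
        n_annotated=n_annot,
        fraction_annotated=n_annot / total_ions if total_ions else 0.0,
        histogram=hist,
        multi_match_mz=sorted(mz_of[i] for i, n in per_ion.items() if n >= 2),
    )


def candidates_to_frame(candidates: list[AnnotationCandidate]) -> pd.DataFrame:
    rows = [
        {
            "ion": c.ion, "mz": c.mz, "record_id": c.record.id, "name": c.record.name,
            "formula": None if c.record.formula is None else formula_to_string(c.record.formula),
            "adduct": c.adduct, "adduct_evidence": c.adduct_evidence,
            "ppm_error": c.ppm_error, "isotope_similarity": c.isotope_similarity,
            "conflicting": c.conflicting, "score": c.score, "rank": c.rank,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows)
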