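"""Quality control and preprocessing for imaging feature matrices.

Three assessments plus the noise-ion filter:

* QC1 — background consistency: Pearson correlation between the mean
  spectra of independently selected background areas.  Stable, clean
  acquisitions show near-identical background spectra (r close to 1).
* Tissue/background classification: tissue-enriched ions (tissue mean /
  background mean > 1) define a per-pixel total-intensity map; a user
  threshold splits pixels into tissue and removable background.
* Noise-ion scoring: for each ion the detection locations (tissue pixels
  with intensity > 0) form a point pattern; a chi-square quadrat test
  against complete spatial randomness (CSR) yields a p-value, and the
  noise score is -log10(p).  CSR-like ions carry no spatial information
  and are filtered below a score threshold (default 30).
* QC2/QC3 — median-intensity summaries and missing-value ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix, ValidationError
from .params import AnalysisParams
from .regions import RegionMask

log = logging.getLogger(__name__)

#: p-values are floored here before -log10, capping the noise score at 300.
P_FLOOR = 1e-300
MAX_NOISE_SCORE = -np.log10(P_FLOOR)


@dataclass
class BackgroundReport:
    labels: list[str]
    mean_spectra: pd.DataFrame       # ions x regions
    correlation: pd.DataFrame        # regions x regions Pearson r


@dataclass
class MissingnessReport:
    pixel_missing_ratio: np.ndarray  # per pixel: fraction of undetected ions
    ion_missing_ratio: np.ndarray    # per ion: fraction of pixels without it


# ---------------------------------------------------------------- QC1

def background_consistency(fm: FeatureMatrix, regions: list[RegionMask]) -> BackgroundReport:
    """Mean spectrum per background region and pairwise Pearson r between them."""
    if len(regions) < 2:
        raise ValidationError("need >= 2 background regions to compare")
    for r in regions:
        r.validate_against(fm)
        if len(r) < 2:
            raise ValidationError(f"region {r.label!r} has < 2 pixels")
    labels = [r.label for r in regions]
    spectra = np.column_stack(
        [fm.intensities[r.pixel_indices].mean(axis=0) for r in regions]
    )
    corr = np.full((len(regions), len(regions)), np.nan)
    sd = spectra.std(axis=0)
    for i in range(len(regions)):
        for j in range(len(regions)):
            if i == j:
                corr[i, j] = 1.0
            elif sd[i] == 0 or sd[j] == 0:
                warnings.warn(
                    f"zero-variance mean spectrum in {labels[i] if sd[i]==0 else labels[j]!r}; "
                    "correlation undefined"
                )
            else:
                corr[i, j] = np.corrcoef(spectra[:, i], spectra[:, j])[0, 1]
    return BackgroundReport(
        labels,
        pd.DataFrame(spectra, index=fm.mz, columns=labels),
        pd.DataFrame(corr, index=labels, columns=labels),
    )


# ------------------------------------------- tissue/background split

def tissue_enriched_ions(fm: FeatureMatrix, tissue: RegionMask,
                         background: RegionMask) -> np.ndarray:
    """Ions with mean(tissue) / mean(background) > 1 (strict).

    A background mean of exactly 0 with any tissue signal counts as
    enriched.  Means include zeros (undetected pixels).
    """
    tissue.validate_against(fm)
    background.validate_against(fm)
    if np.intersect1d(tissue.pixel_indices, background.pixel_indices).size:
        raise ValidationError("tissue and background masks overlap")
    mt = fm.intensities[tissue.pixel_indices].mean(axis=0)
    mb = fm.intensities[background.pixel_indices].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enriched = np.where(mb > 0, mt / mb > 1, mt > 0)
    return np.flatnonzero(enriched)


def classify_pixels(fm: FeatureMatrix, enriched_ions: np.ndarray,
                    intensity_threshold: float) -> tuple[RegionMask, RegionMask]:
    """Split pixels by total intensity over tissue-enriched ions.

    Pixels at or above the threshold become tissue, the rest background.
    Monotone in the threshold: raising it never adds tissue pixels.
    """
    enriched_ions = np.asarray(enriched_ions, dtype=int)
    if enriched_ions.size == 0:
        raise ValidationError("enriched ion set is empty")
    if intensity_threshold <= 0:
        raise ValidationError("intensity threshold must be > 0")
    totals = fm.intensities[:, enriched_ions].sum(axis=1)
    is_tissue = totals >= intensity_threshold
    if not is_tissue.any():
        raise ValidationError("threshold excludes all pixels (empty tissue)")
    tissue = RegionMask("tissue", np.flatnonzero(is_tissue))
    background = RegionMask("background", np.flatnonzero(~is_tissue), allow_empty=True)
    return tissue, background


def suggest_tissue_threshold(fm: FeatureMatrix, enriched_ions: np.ndarray) -> float:
    """Otsu threshold on log10(total + 1) as a starting proposal."""
    from skimage.filters import threshold_otsu

    totals = fm.intensities[:, np.asarray(enriched_ions, dtype=int)].sum(axis=1)
    t = threshold_otsu(np.log10(totals + 1.0))
    return float(10 ** t - 1.0)


def remove_background(fm: FeatureMatrix, tissue: RegionMask) -> FeatureMatrix:
    """Drop all rows outside the tissue mask (they become off-slide)."""
    tissue.validate_against(fm)
    return fm.subset_pixels(tissue.pixel_indices)


# ------------------------------------------------- CSR quadrat test

def _quadrat_labels(coords: np.ndarray, gx: int, gy: int) -> np.ndarray:
    """Assign each pixel to a quadrat of the gx x gy partition of the bbox."""
    x, y = coords[:, 0], coords[:, 1]
    x0, x1 = x.min(), x.max()
    y0, y1 = y.min(), y.max()
    qx = np.minimum(((x - x0) * gx) // max(x1 - x0 + 1, 1), gx - 1).astype(int)
    qy = np.minimum(((y - y0) * gy) // max(y1 - y0 + 1, 1), gy - 1).astype(int)
    return qx * gy + qy


def _grid_ladder(gx: int, gy: int) -> list[tuple[int, int]]:
    """Successively coarser grids (halving the larger side), ending at 2 cells."""
    ladder = [(gx, gy)]
    while gx * gy > 2:
        if gx >= gy:
            gx = max(1, gx // 2)
        else:
            gy = max(1, gy // 2)
        if gx * gy < 2:
            gx, gy = 2, 1
        if (gx, gy) == ladder[-1]:
            break
        ladder.append((gx, gy))
    return ladder


def noise_scores(fm: FeatureMatrix, tissue: RegionMask,
                 grid: tuple[int, int] | None = None,
                 params: AnalysisParams | None = None,
                 two_sided: bool = True) -> pd.DataFrame:
    """Quadrat chi-square test of CSR per ion, over tissue pixels.

    Tissue pixels are partitioned into quadrats over their bounding box;
    quadrats containing no tissue pixel are dropped.  For an ion with n
    detections, the expected count in quadrat q is n * (pixels in q) /
    (total tissue pixels).  The grid is coarsened per ion until the mean
    expected count per quadrat is >= 1 (chi-square validity), down to a
    2-cell minimum.

    Because detections live on a finite pixel lattice (at most one per
    pixel), quadrat counts given n are multivariate hypergeometric, not
    multinomial: their variance carries the finite-population factor
    (N - n)/(N - 1).  The Pearson statistic is divided by that factor so
    that its null distribution stays chi-square even when a sizable
    fraction of the tissue is detected; for sparse ions the factor is ~1
    and the classical quadrat test is recovered.

    The p-value is two-sided by default (the smaller chi-square tail
    doubled, capped at 1), matching the spatstat quadrat test
    convention; ``two_sided=False`` gives the upper tail only.

    Returns a table with columns mz, n_detections, statistic, df,
    p_value, noise_score, is_noise.  Two degenerate patterns carry no
    usable spatial information and get score 0 with a flag: ions with
    zero detections in tissue, and saturated ions detected at every
    tissue pixel (whose counts equal the expectation by construction,
    not by randomness).
    """
    params = params or AnalysisParams()
    grid = grid or params.quadrat_grid
    tissue.validate_against(fm)
    tidx = tissue.pixel_indices
    coords = fm.coords[tidx]
    detected = fm.intensities[tidx] > 0
    n_tissue = len(tidx)
    n_det = detected.sum(axis=0)

    ladder = _grid_ladder(*grid)
    # per grid level: quadrat labels, pixel counts per (non-empty) quadrat
    levels = []
    for gx, gy in ladder:
        lab = _quadrat_labels(coords, gx, gy)
        uniq, inv = np.unique(lab, return_inverse=True)
        npix = np.bincount(inv)
        levels.append((inv, npix, len(uniq)))

    stat = np.zeros(fm.n_ions)
    dof = np.zeros(fm.n_ions, dtype=int)
    pval = np.ones(fm.n_ions)
    flagged_empty = (n_det == 0) | (n_det == n_tissue)

    # group ions by the grid level they need, then vectorize per group
    level_of_ion = np.zeros(fm.n_ions, dtype=int)
    for j in range(fm.n_ions):
        if flagged_empty[j]:
            continue
        for li, (_, _, k) in enumerate(levels):
            if n_det[j] >= k or li == len(levels) - 1:
                level_of_ion[j] = li
                break
    for li, (inv, npix, k) in enumerate(levels):
        ions = np.flatnonzero((level_of_ion == li) & ~flagged_empty)
        if ions.size == 0:
            continue
        # observed counts per quadrat: k x len(ions)
        obs = np.zeros((k, ions.size))
        np.add.at(obs, inv, detected[:, ions].astype(float))
        expected = np.outer(npix / n_tissue, n_det[ions].astype(float))
        x2 = ((obs - expected) ** 2 / expected).sum(axis=0)
        # finite-population correction: lattice counts are hypergeometric,
        # so the reference distribution is chi-square for x2 / fpc
        fpc = (n_tissue - n_det[ions]) / (n_tissue - 1)
        x2_adj = x2 / fpc
        df = k - 1
        upper = stats.chi2.sf(x2_adj, df)
        if two_sided:
            lower = stats.chi2.cdf(x2_adj, df)
            p = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
        else:
            p = upper
        stat[ions] = x2  # raw Pearson statistic; p-values use the corrected form
        dof[ions] = df
        pval[ions] = p

    score = -np.log10(np.maximum(pval, P_FLOOR))
    score[flagged_empty] = 0.0
    pval[n_det == 0] = np.nan
    pval[n_det == n_tissue] = 1.0
    table = pd.DataFrame(
        {
            "mz": fm.mz,
            "n_detections": n_det,
            "statistic": stat,
            "df": dof,
            "p_value": pval,
            "noise_score": score,
            "degenerate": flagged_empty,
        }
    )
    table["is_noise"] = table["noise_score"] < params.noise_score_threshold
    return table


def filter_noise(fm: FeatureMatrix, table: pd.DataFrame, threshold: float) -> FeatureMatrix:
    """Drop ions whose noise score is below ``threshold``."""
    if len(table) != fm.n_ions:
        raise ValidationError("noise-score table does not cover all ions")
    keep = np.flatnonzero(table["noise_score"].to_numpy() >= threshold)
    if keep.size == 0:
        raise ValidationError(f"threshold {threshold} removes every ion")
    log.info("noise filter: retaining %d/%d ions (%.1f%%)",
             keep.size, fm.n_ions, 100 * keep.size / fm.n_ions)
    return fm.subset_ions(keep)


# --------------------------------------------------------- QC2 / QC3

def intensity_summaries(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-pixel median over detected ions, per-ion median over detected pixels).

    Medians ignore zeros (undetected); a pixel or ion with no detections
    yields NaN with a warning.
    """
    if fm.n_pixels == 0 or fm.n_ions == 0:
        raise ValidationError("empty matrix")
    masked = np.where(fm.intensities > 0, fm.intensities, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        pixel_med = np.nanmedian(masked, axis=1)
        ion_med = np.nanmedian(masked, axis=0)
    if np.isnan(pixel_med).any():
        warnings.warn(f"{int(np.isnan(pixel_med).sum())} pixels have no detected ions")
    if np.isnan(ion_med).any():
        warnings.warn(f"{int(np.isnan(ion_med).sum())} ions are detected nowhere")
    return pixel_med, ion_med


def missing_stats(fm: FeatureMatrix) -> MissingnessReport:
    """Per-pixel and per-ion fractions of zero (undetected) cells."""
    if fm.n_pixels == 0 or fm.n_ions == 0:
        raise ValidationError("empty matrix")
    zero = fm.intensities == 0
    return MissingnessReport(zero.mean(axis=1), zero.mean(axis=0))
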