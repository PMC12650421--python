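"""Two-group differential analysis over pixels.

Groups come either from pixel-cluster ids or from user ROIs.  All
pixels of a group are treated as samples; each ion is tested with a
two-sided Wilcoxon rank-sum test (exact enumeration when both groups
have at most 25 pixels and the data are tie-free, otherwise the normal
approximation with tie correction), fold changes are log2 ratios of
group means with a small pseudocount, and p-values are adjusted across
all ions with Benjamini-Hochberg.  Default significance: fold change
> 2 or < 0.5 and adjusted p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import FeatureMatrix, ValidationError
from .params import AnalysisParams
from .patterns import ClusterAssignment
from .regions import RegionMask


@dataclass
class GroupLabels:
    labels: np.ndarray  # per-pixel: "case" | "control" | "unused"
    provenance: str

    @property
    def case(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "case")

    @property
    def control(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "control")


def groups_from_clusters(assignment: ClusterAssignment,
                         case_ids, control_ids) -> GroupLabels:
    case_ids, control_ids = set(case_ids), set(control_ids)
    if not case_ids or not control_ids:
        raise ValidationError("case and control cluster sets must be non-empty")
    if case_ids & control_ids:
        raise ValidationError(f"clusters {sorted(case_ids & control_ids)} in both groups")
    present = set(np.unique(assignment.labels).tolist())
    missing = (case_ids | control_ids) - present
    if missing:
        raise ValidationError(f"cluster ids {sorted(missing)} not present in assignment")
    labels = np.array(["unused"] * len(assignment.labels), dtype=object)
    labels[np.isin(assignment.labels, list(case_ids))] = "case"
    labels[np.isin(assignment.labels, list(control_ids))] = "control"
    return GroupLabels(labels, f"clusters case={sorted(case_ids)} control={sorted(control_ids)}")


def groups_from_rois(fm: FeatureMatrix, case_rois: list[RegionMask],
                     control_rois: list[RegionMask]) -> GroupLabels:
    if not case_rois or not control_rois:
        raise ValidationError("need >= 1 ROI per group")
    for r in case_rois + control_rois:
        r.validate_against(fm)
    case = np.unique(np.concatenate([r.pixel_indices for r in case_rois]))
    ctrl = np.unique(np.concatenate([r.pixel_indices for r in control_rois]))
    if np.intersect1d(case, ctrl).size:
        raise ValidationError("case and control ROIs overlap")
    labels = np.array(["unused"] * fm.n_pixels, dtype=object)
    labels[case] = "case"
    labels[ctrl] = "control"
    return GroupLabels(
        labels,
        f"rois case={[r.label for r in case_rois]} control={[r.label for r in control_rois]}",
    )


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small tie-free samples."""
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0  # all observations identical: no evidence either way
    pooled = np.concatenate([a, b])
    exact = len(a) <= 25 and len(b) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def differential_test(fm: FeatureMatrix, groups: GroupLabels,
                      pseudocount: float | None = None,
                      min_detection_fraction: float = 0.0) -> pd.DataFrame:
    """Per-ion Wilcoxon rank-sum test between case and control pixels.

    ``pseudocount`` stabilizes the log2 fold change of means; the
    default is 1e-9 times the global intensity maximum.  An optional
    detection-fraction prefilter (off by default) excludes ions detected
    in fewer than the given fraction of pixels in both groups from
    testing; excluded ions get p = q = NaN.
    """
    case_idx, ctrl_idx = groups.case, groups.control
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValidationError("each group needs >= 2 pixels")
    A = fm.intensities[case_idx]
    B = fm.intensities[ctrl_idx]
    c = pseudocount if pseudocount is not None else 1e-9 * max(fm.intensities.max(), 1.0)
    mean_case = A.mean(axis=0)
    mean_ctrl = B.mean(axis=0)
    log2fc = np.log2((mean_case + c) / (mean_ctrl + c))

    tested = np.ones(fm.n_ions, dtype=bool)
    if min_detection_fraction > 0:
        det_a = (A > 0).mean(axis=0)
        det_b = (B > 0).mean(axis=0)
        tested = (det_a >= min_detection_fraction) | (det_b >= min_detection_fraction)

    pvals = np.full(fm.n_ions, np.nan)
    small = len(case_idx) <= 25 and len(ctrl_idx) <= 25
    if small:
        for j in np.flatnonzero(tested):
            pvals[j] = _wilcoxon_p(A[:, j], B[:, j])
    else:
        cols = np.flatnonzero(tested)
        if cols.size:
            res = stats.mannwhitneyu(A[:, cols], B[:, cols], axis=0,
                                     alternative="two-sided", method="asymptotic")
            pvals[cols] = res.pvalue
            # a column where every value is identical yields NaN from the
            # tie-corrected normal approximation; that is "no evidence"
            degenerate = np.ptp(np.vstack([A[:, cols], B[:, cols]]), axis=0) == 0
            pvals[cols[degenerate]] = 1.0

    qvals = np.full(fm.n_ions, np.nan)
    mask = np.isfinite(pvals)
    if mask.any():
        qvals[mask] = multipletests(pvals[mask], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "mz": fm.mz,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": qvals,
            "tested": tested,
        }
    )


def significant_ions(result: pd.DataFrame,
                     params: AnalysisParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(up, down) ion index lists at the fold-change and FDR thresholds."""
    params = params or AnalysisParams()
    q = result["q_value"].to_numpy()
    fc = result["log2fc"].to_numpy()
    sig = np.isfinite(q) & (q < params.fdr_alpha)
    up = np.flatnonzero(sig & (fc >= params.log2fc_hi))
    down = np.flatnonzero(sig & (fc <= params.log2fc_lo))
    return up, down
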