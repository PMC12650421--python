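"""Single-ion images, RGB composites and colocalization ranking.

Images follow the raster convention: y increases downward, origin at
(min x, min y) of the observed pixels.  Grid cells with no observed
pixel (off-slide, e.g. removed background) are NaN, distinct from an
intensity of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, ValidationError


@dataclass
class IonImage:
    mz: float
    grid: np.ndarray   # (height, width) float with NaN off-slide
    x0: int
    y0: int


class AmbiguousIonError(ValidationError):
    def __init__(self, mz_query, candidates):
        self.candidates = list(candidates)
        super().__init__(
            f"query m/z {mz_query} matches {len(self.candidates)} ions: "
            f"{[round(c, 5) for c in self.candidates]}"
        )


def resolve_ion(fm: FeatureMatrix, mz_query: float, tol: float) -> int:
    hits = fm.ions_near(mz_query, tol)
    if len(hits) == 0:
        raise AmbiguousIonError(mz_query, [])
    if len(hits) > 1:
        raise AmbiguousIonError(mz_query, fm.mz[hits])
    return int(hits[0])


def _blank_grid(fm: FeatureMatrix) -> tuple[np.ndarray, int, int]:
    x0, y0, x1, y1 = fm.bounding_box()
    grid = np.full((y1 - y0 + 1, x1 - x0 + 1), np.nan)
    return grid, x0, y0


def ion_image(fm: FeatureMatrix, mz_query: float, tol: float = 0.01) -> IonImage:
    """Spatial distribution map of the single ion matching the query."""
    j = resolve_ion(fm, mz_query, tol)
    grid, x0, y0 = _blank_grid(fm)
    grid[fm.coords[:, 1] - y0, fm.coords[:, 0] - x0] = fm.intensities[:, j]
    return IonImage(float(fm.mz[j]), grid, x0, y0)


def rgb_composite(fm: FeatureMatrix, mz_list, tol: float = 0.01,
                  percentile: float = 99.0) -> np.ndarray:
    """Map 2-3 ion images to RGB channels.

    Each channel is independently scaled to [0, 1] by its upper
    percentile over observed pixels (hot-pixel resistant), then clipped.
    With two ions the blue channel stays zero.  Off-slide cells are NaN
    in all channels.
    """
    if len(mz_list) not in (2, 3):
        raise ValidationError("rgb_composite needs 2 or 3 ion queries")
    grid, x0, y0 = _blank_grid(fm)
    out = np.stack([grid.copy(), grid.copy(), grid.copy()], axis=-1)
    rows = fm.coords[:, 1] - y0
    cols = fm.coords[:, 0] - x0
    out[rows, cols, :] = 0.0
    for ch, q in enumerate(mz_list):
        j = resolve_ion(fm, q, tol)
        v = fm.intensities[:, j]
        top = np.percentile(v, percentile)
        scaled = np.clip(v / top, 0.0, 1.0) if top > 0 else np.zeros_like(v)
        out[rows, cols, ch] = scaled
    return out


def colocalization(fm: FeatureMatrix, target_mz: float, tol: float = 0.01,
                   n_top: int = 6) -> dict:
    """Pearson correlation of every ion against a target ion.

    Returns the full ranking plus the ``n_top`` most positively and most
    negatively correlated ions (the default six of each mirrors standard
    colocalization panels).  Zero-variance ions are excluded from the
    ranking; a zero-variance target is an error.
    """
    j = resolve_ion(fm, target_mz, tol)
    x = fm.intensities[:, j]
    if x.std() == 0:
        raise ValidationError(f"target ion {fm.mz[j]} has zero variance")
    X = fm.intensities
    zx = x - x.mean()
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Z.T @ zx) / (len(x) * sd * x.std())
    table = pd.DataFrame({"ion": np.arange(fm.n_ions), "mz": fm.mz, "pearson_r": r})
    table = table[(table["ion"] != j) & np.isfinite(table["pearson_r"])]
    table = table.sort_values("pearson_r", ascending=False).reset_index(drop=True)
    return {
        "target_ion": j,
        "target_mz": float(fm.mz[j]),
        "ranking": table,
        "top_positive": table.head(n_top),
        "top_negative": table.tail(n_top).iloc[::-1],
    }


def save_image(grid: np.ndarray, path, cmap: str = "viridis", title: str | None = None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if grid.ndim == 3:
        ax.imshow(grid, interpolation="nearest")
    else:
        im = ax.imshow(grid, cmap=cmap, interpolation="nearest")
        fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
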