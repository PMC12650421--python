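"""Region masks: named pixel sets (tissue, background areas, ROIs).

Regions replace interactive delineation: they are supplied as explicit
pixel lists or as polygons in grid units, rasterized by testing each
pixel center for containment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, ValidationError


@dataclass
class RegionMask:
    label: str
    pixel_indices: np.ndarray  # row indices into the feature matrix
    allow_empty: bool = False  # only for derived masks (e.g. empty background)

    def __post_init__(self):
        self.pixel_indices = np.unique(np.asarray(self.pixel_indices, dtype=int))
        if len(self.pixel_indices) == 0 and not self.allow_empty:
            raise ValidationError(f"region {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.pixel_indices)

    def validate_against(self, fm: FeatureMatrix) -> None:
        if len(self.pixel_indices) == 0:
            return
        if self.pixel_indices.min() < 0 or self.pixel_indices.max() >= fm.n_pixels:
            raise ValidationError(
                f"region {self.label!r} references pixels outside the matrix"
            )


def mask_from_pixels(fm: FeatureMatrix, label: str, pixels) -> RegionMask:
    """Build a mask from explicit (x, y) pairs; unknown pixels are rejected."""
    index = fm.pixel_index()
    idx = []
    for x, y in pixels:
        key = (int(x), int(y))
        if key not in index:
            raise ValidationError(f"region {label!r}: pixel {key} not in matrix")
        idx.append(index[key])
    return RegionMask(label, np.array(idx))


def mask_from_polygon(fm: FeatureMatrix, label: str, vertices) -> RegionMask:
    """Rasterize a polygon (grid units) to the pixels whose centers it contains."""
    from matplotlib.path import Path

    poly = Path(np.asarray(vertices, dtype=float))
    inside = poly.contains_points(fm.coords.astype(float), radius=1e-9)
    idx = np.flatnonzero(inside)
    if len(idx) == 0:
        raise ValidationError(f"polygon region {label!r} contains no pixels")
    return RegionMask(label, idx)


def read_regions_csv(fm: FeatureMatrix, path) -> dict[str, RegionMask]:
    """Read regions from CSV.

    Two layouts are supported: explicit pixels (label, x, y) and polygons
    (label, x, y, vertex_order); the presence of a vertex_order column
    selects polygon mode.
    """
    df = pd.read_csv(path)
    need = {"label", "x", "y"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: region file needs columns {sorted(need)}")
    out: dict[str, RegionMask] = {}
    polygon_mode = "vertex_order" in df.columns
    for label, grp in df.groupby("label", sort=False):
        if polygon_mode:
            grp = grp.sort_values("vertex_order")
            out[str(label)] = mask_from_polygon(
                fm, str(label), grp[["x", "y"]].to_numpy()
            )
        else:
            out[str(label)] = mask_from_pixels(
                fm, str(label), grp[["x", "y"]].to_numpy()
            )
    return out
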