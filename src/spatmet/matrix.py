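"""The pixel-by-ion feature matrix: the universal currency of the workflow.

Input is delimited text whose first two columns are integer X and Y pixel
coordinates and whose remaining column headers are m/z values in Daltons;
cells hold ion intensities, with zero meaning "not detected".  The pixel
grid is the bounding box of the observed coordinates; grid cells without
a row are "off-slide" (e.g. background pixels removed during QC), which
is distinct from an intensity of zero.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Unparseable input file (bad header, wrong column layout...)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a data invariant."""


@dataclass
class FeatureMatrix:
    coords: np.ndarray      # (n_pixels, 2) int, unique (x, y)
    mz: np.ndarray          # (n_ions,) float, strictly increasing
    intensities: np.ndarray  # (n_pixels, n_ions) float, >= 0, finite

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n, 2) array")
        if self.intensities.shape != (len(self.coords), len(self.mz)):
            raise ValidationError(
                f"intensity shape {self.intensities.shape} does not match "
                f"{len(self.coords)} pixels x {len(self.mz)} ions"
            )
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValidationError("duplicate (x, y) pixel coordinates")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("non-finite intensity values")
        if np.any(self.intensities < 0):
            raise ValidationError("negative intensity values")
        # canonical m/z order
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensities = self.intensities[:, order]
            if np.any(np.diff(self.mz) == 0):
                dup = self.mz[:-1][np.diff(self.mz) == 0]
                raise ValidationError(f"duplicate m/z columns after parsing: {dup[:5]}")

    # -- basic queries -------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_ions(self) -> int:
        return len(self.mz)

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(xmin, ymin, xmax, ymax) of observed pixels."""
        return (
            int(self.coords[:, 0].min()), int(self.coords[:, 1].min()),
            int(self.coords[:, 0].max()), int(self.coords[:, 1].max()),
        )

    def pixel_index(self) -> dict[tuple[int, int], int]:
        return {(int(x), int(y)): i for i, (x, y) in enumerate(self.coords)}

    def ions_near(self, mz_query: float, tol: float) -> np.ndarray:
        """Indices of ions within ``tol`` Da of ``mz_query``."""
        lo = np.searchsorted(self.mz, mz_query - tol, side="left")
        hi = np.searchsorted(self.mz, mz_query + tol, side="right")
        return np.arange(lo, hi)

    # -- subsetting ----------------------------------------------------
    def subset_pixels(self, rows: np.ndarray) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(self.coords[rows], self.mz.copy(), self.intensities[rows])

    def subset_ions(self, cols: np.ndarray) -> "FeatureMatrix":
        cols = np.asarray(cols)
        return FeatureMatrix(self.coords.copy(), self.mz[cols], self.intensities[:, cols])

    def drop_ions(self, cols) -> "FeatureMatrix":
        keep = np.setdiff1d(np.arange(self.n_ions), np.asarray(list(cols), dtype=int))
        return self.subset_ions(keep)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=[repr(float(v)) for v in self.mz])
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        return df


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_feature_matrix(path, delimiter: str | None = None) -> FeatureMatrix:
    """Read a delimited feature matrix (x, y, then m/z columns).

    Column headers after the two coordinate columns must parse as decimal
    m/z values; the full printed precision is kept.  Rows with missing
    coordinates are dropped with a warning; duplicate coordinates or
    negative intensities raise :class:`ValidationError`.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: need >= 2 coordinate columns plus >= 1 m/z column, "
            f"got {df.shape[1]} columns"
        )
    mz_cols = df.columns[2:]
    mz = np.empty(len(mz_cols))
    for k, c in enumerate(mz_cols):
        try:
            mz[k] = float(str(c).strip())
        except ValueError:
            raise FormatError(f"{path}: m/z column header {c!r} is not numeric") from None
    bad = df.iloc[:, 0].isna() | df.iloc[:, 1].isna()
    if bad.any():
        warnings.warn(f"{path}: dropping {int(bad.sum())} rows with missing coordinates")
        df = df.loc[~bad]
    if len(df) == 0:
        raise FormatError(f"{path}: no rows with valid coordinates")
    coords = df.iloc[:, :2].to_numpy(dtype=float)
    if not np.allclose(coords, np.round(coords)):
        raise ValidationError(f"{path}: non-integer pixel coordinates")
    inten = df.iloc[:, 2:].to_numpy(dtype=float)
    inten = np.nan_to_num(inten, nan=0.0)  # empty cells mean not detected
    return FeatureMatrix(coords.astype(int), mz, inten)


def write_feature_matrix(fm: FeatureMatrix, path, delimiter: str = ",") -> None:
    """Write a matrix so that re-reading reproduces it (repr-precision m/z)."""
    fm.to_frame().to_csv(path, sep=delimiter, index=False)
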