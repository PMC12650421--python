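"""Grid-adjacency spatial weights and bivariate Moran's I.

The spatial cross-correlation used to confirm isotope and adduct pairs:
two peaks arising from the same molecule must light up the same tissue
structures, which bivariate Moran's I quantifies under a row-standardized
neighbor weight matrix W:

    I_ab = (n / S0) * (z_a' W z_b) / sqrt((z_a' z_a) (z_b' z_b))

with z the mean-centered intensity vectors and S0 the sum of all
weights; both variables are standardized so the statistic does not
depend on either ion's intensity scale.  Because W need not be
symmetric, the reported statistic symmetrizes the numerator:
(z_a' W z_b + z_b' W z_a) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse


@dataclass
class SpatialWeights:
    """Row-standardized sparse neighbor weights over a pixel set."""

    W: sparse.csr_matrix
    isolated: np.ndarray  # boolean: pixels with no neighbor (zero row)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def s0(self) -> float:
        return float(self.W.sum())


_ROOK = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_QUEEN = _ROOK + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def build_spatial_weights(coords: np.ndarray, scheme: str = "queen") -> SpatialWeights:
    """Grid adjacency among the given pixels, row-standardized.

    ``scheme`` is "rook" (4-neighborhood) or "queen" (8-neighborhood).
    Pixels with no neighbor in the set get an all-zero row and are
    flagged as isolated.
    """
    coords = np.asarray(coords, dtype=int)
    if len(coords) < 2:
        raise ValueError("need >= 2 pixels to build spatial weights")
    offsets = {"rook": _ROOK, "queen": _QUEEN}.get(scheme)
    if offsets is None:
        raise ValueError(f"unknown scheme {scheme!r}; use 'rook' or 'queen'")
    index = {(int(x), int(y)): i for i, (x, y) in enumerate(coords)}
    rows, cols = [], []
    for i, (x, y) in enumerate(coords):
        for dx, dy in offsets:
            j = index.get((int(x) + dx, int(y) + dy))
            if j is not None:
                rows.append(i)
                cols.append(j)
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(coords), len(coords))
    )
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} pixels have no neighbors (zero weight row)")
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    W = sparse.diags(inv) @ A
    return SpatialWeights(W.tocsr(), isolated)


def bivariate_moran(x: np.ndarray, y: np.ndarray, weights: SpatialWeights) -> float:
    """Symmetrized bivariate Moran's I between two pixel-indexed variables.

    Returns NaN (with a warning) if either variable has zero variance.
    With row-standardized weights and no isolated pixels, n/S0 = 1 and a
    perfect rook-adjacency checkerboard against itself gives exactly -1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) != weights.n:
        raise ValueError("x, y must be 1-D and match the weight matrix size")
    zx = x - x.mean()
    zy = y - y.mean()
    sxx = zx @ zx
    syy = zy @ zy
    if sxx == 0 or syy == 0:
        warnings.warn("zero-variance variable in Moran's I; returning NaN")
        return float("nan")
    scale = weights.n / weights.s0
    num = 0.5 * (zx @ (weights.W @ zy) + zy @ (weights.W @ zx))
    return float(scale * num / np.sqrt(sxx * syy))


def moran_matrix_prepare(intensities: np.ndarray, weights: SpatialWeights):
    """Precompute centered columns and their lagged versions for fast pairwise I.

    Returns (Z, WZ, ss) where Z is pixel x ion mean-centered intensities,
    WZ = W @ Z, and ss the per-ion sum of squares.  Then
    I_ab = (n/S0) * (Z_a.WZ_b + Z_b.WZ_a) / (2 sqrt(ss_a ss_b)).
    """
    Z = intensities - intensities.mean(axis=0, keepdims=True)
    WZ = weights.W @ Z
    ss = (Z * Z).sum(axis=0)
    return Z, WZ, ss


def bivariate_moran_pairs(pairs: np.ndarray, Z, WZ, ss, weights: SpatialWeights) -> np.ndarray:
    """Vectorized symmetrized Moran's I for an array of (a, b) ion index pairs."""
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return np.zeros(0)
    a, b = pairs[:, 0], pairs[:, 1]
    scale = weights.n / weights.s0
    num_ab = np.einsum("ij,ij->j", Z[:, a], WZ[:, b])
    num_ba = np.einsum("ij,ij->j", Z[:, b], WZ[:, a])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * scale * (num_ab + num_ba) / np.sqrt(ss[a] * ss[b])
    return out
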