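"""Dual-dimension spatial structure discovery.

Pixel dimension: pixels are clustered by their whole metabolic profile
(total-intensity normalization, log1p, per-ion z-score, PCA) using
either Louvain communities on a shared-nearest-neighbor graph or
k-means on a 2-D UMAP embedding.

Ion dimension: each ion's image is normalized to unit sum, smoothed
with a local mean filter over the tissue pixels, and ions are grouped
by k-means on these spatial profiles.  Ions in one cluster share a
spatial expression program (co-expression pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import FeatureMatrix, ValidationError
from .params import AnalysisParams
from .spatial import build_spatial_weights

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: np.ndarray       # per-pixel cluster id, contiguous from 1
    method: str
    params: dict
    seed: int

    @property
    def k(self) -> int:
        return int(self.labels.max())


@dataclass
class PatternSet:
    ion_labels: np.ndarray   # per-ion pattern id, contiguous from 1
    members: dict            # pattern id -> list of ion indices
    mean_patterns: np.ndarray  # k x n_pixels, each row scaled to max 1


def preprocess_for_clustering(fm: FeatureMatrix,
                              params: AnalysisParams | None = None) -> np.ndarray:
    """Pixel embedding: size-factor normalize, log1p, z-score, PCA.

    Deterministic given the data (full SVD, sign convention: each
    component's largest-magnitude loading is positive).
    """
    from sklearn.decomposition import PCA

    params = params or AnalysisParams()
    if fm.n_pixels < 2 or fm.n_ions < 2:
        raise ValidationError("need >= 2 pixels and >= 2 ions")
    X = fm.intensities.astype(float)
    totals = X.sum(axis=1)
    if np.all(totals == totals[0]) and np.all(X == X[0]):
        raise ValidationError("constant matrix cannot be clustered")
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    sf = np.where(totals > 0, totals / med, 1.0)
    X = np.log1p(X / sf[:, None])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    k = min(params.pca_dims, fm.n_pixels - 1, fm.n_ions)
    pca = PCA(n_components=k, svd_solver="full")
    emb = pca.fit_transform(X)
    # fix component signs for reproducibility across BLAS variants
    signs = np.sign(pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return emb * signs


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k by order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    seen: dict = {}
    for i, l in enumerate(labels):
        if l not in seen:
            seen[l] = len(seen) + 1
        out[i] = seen[l]
    return out


def pixel_clusters(fm: FeatureMatrix, method: str = "umap-kmeans",
                   params: AnalysisParams | None = None,
                   k: int | None = None) -> ClusterAssignment:
    """Cluster pixels by metabolic profile.

    ``method`` is "louvain" (shared-nearest-neighbor graph + Louvain
    modularity communities) or "umap-kmeans" (2-D UMAP then k-means with
    ``k`` clusters).  "LM" and "SLM" are accepted as aliases of louvain
    with a logged notice.  Deterministic under a fixed seed.
    """
    params = params or AnalysisParams()
    seed = params.random_seed
    emb = preprocess_for_clustering(fm, params)
    method_l = method.lower()
    if method_l in ("lm", "slm", "louvain-lm", "louvain-slm"):
        log.info("method %s mapped to louvain", method)
        method_l = "louvain"

    if method_l == "louvain":
        labels = _louvain_labels(emb, params.knn_k, seed)
    elif method_l in ("umap-kmeans", "umap_kmeans"):
        k = k or params.kmeans_k
        if k is None:
            raise ValidationError("umap-kmeans needs a cluster count k")
        if k > fm.n_pixels:
            raise ValidationError(f"k={k} exceeds pixel count {fm.n_pixels}")
        labels = _umap_kmeans_labels(emb, k, seed)
    else:
        raise ValidationError(f"unknown clustering method {method!r}")
    return ClusterAssignment(_relabel(labels), method_l,
                             {"k": k, "knn_k": params.knn_k}, seed)


def _louvain_labels(emb: np.ndarray, knn_k: int, seed: int) -> np.ndarray:
    import networkx as nx
    from sklearn.neighbors import NearestNeighbors

    k = min(knn_k, len(emb) - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    knn = nn.kneighbors_graph(emb, mode="connectivity")
    # shared-nearest-neighbor weights (Jaccard of neighbor sets)
    shared = (knn @ knn.T).tocoo()
    g = nx.Graph()
    g.add_nodes_from(range(len(emb)))
    for i, j, s in zip(shared.row, shared.col, shared.data):
        if i < j and s > 0:
            jac = s / (2 * k - s)
            if jac > 1 / 15:  # Seurat-style pruning of weak SNN edges
                g.add_edge(int(i), int(j), weight=float(jac))
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    labels = np.zeros(len(emb), dtype=int)
    for ci, members in enumerate(comms, start=1):
        labels[list(members)] = ci
    return labels


def _umap_kmeans_labels(emb: np.ndarray, k: int, seed: int) -> np.ndarray:
    import umap
    from sklearn.cluster import KMeans

    reducer = umap.UMAP(n_neighbors=30, min_dist=0.1, n_components=2,
                        random_state=seed)
    xy = reducer.fit_transform(emb)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(xy) + 1


def ion_pattern_clusters(fm: FeatureMatrix, k: int,
                         params: AnalysisParams | None = None) -> PatternSet:
    """Group ions by the similarity of their spatial expression patterns.

    Each ion image is normalized to unit sum and smoothed with a local
    mean over the 3x3 neighborhood restricted to observed pixels; the
    resulting profiles are clustered with k-means.  Ions that are
    detected nowhere cannot carry a pattern and raise an error if all
    ions are empty.
    """
    from sklearn.cluster import KMeans

    params = params or AnalysisParams()
    if k < 1 or k > fm.n_ions:
        raise ValidationError(f"pattern count k={k} must be in [1, {fm.n_ions}]")
    X = fm.intensities.astype(float)
    sums = X.sum(axis=0)
    if np.any(sums == 0):
        raise ValidationError("ion(s) with zero total intensity; filter them first")
    P = X / sums  # unit-sum images, pixel x ion
    # 3x3 mean filter over observed pixels: (self + neighbors)/count
    w = build_spatial_weights(fm.coords, "queen")
    deg = np.asarray((w.W > 0).sum(axis=1)).ravel()
    S = (w.W.multiply(deg[:, None]) @ P + P) / (deg + 1)[:, None]
    profiles = S.T  # ion x pixel
    km = KMeans(n_clusters=k, n_init=10, random_state=params.random_seed)
    labels = km.fit_predict(profiles) + 1
    labels = _relabel(labels)
    members = {int(c): np.flatnonzero(labels == c).tolist()
               for c in range(1, labels.max() + 1)}
    means = np.vstack([profiles[members[c]].mean(axis=0)
                       for c in range(1, labels.max() + 1)])
    means = means / means.max(axis=1, keepdims=True)
    return PatternSet(labels, members, means)
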