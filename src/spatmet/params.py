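"""Shared analysis parameters with workflow defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class AnalysisParams:
    """All tunable thresholds of the downstream workflow.

    ppm_tolerance
        Relative mass-matching window (parts per million), default 10.
    spatial_correlation_threshold
        Bivariate Moran's I needed to confirm an isotope or adduct pair
        (rho, default 0.5).
    noise_score_threshold
        Ions whose quadrat-test noise score (-log10 p) falls below this
        are treated as noise; default 30.
    quadrat_grid
        Default quadrat partition of the tissue bounding box (8 x 8),
        auto-shrunk per ion so the mean expected count per quadrat >= 1.
    log2fc_hi / log2fc_lo, fdr_alpha
        Differential significance: |log2 FC| >= 1 (fold change > 2 or
        < 0.5) and BH-adjusted p < 0.01.
    score_weights
        (mass accuracy, isotope similarity, adduct evidence) weights of
        the composite annotation score; must be >= 0 and sum to 1.
    """

    ppm_tolerance: float = 10.0
    spatial_correlation_threshold: float = 0.5
    noise_score_threshold: float = 30.0
    quadrat_grid: tuple[int, int] = (8, 8)
    log2fc_hi: float = 1.0
    log2fc_lo: float = -1.0
    fdr_alpha: float = 0.01
    pca_dims: int = 30
    knn_k: int = 20
    kmeans_k: int | None = None
    pattern_k: int | None = None
    score_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    isotope_prune: float = 1e-3
    pattern_match_tol: float = 0.01  # Da, peak matching in entropy similarity
    rgb_percentile: float = 99.0
    random_seed: int = 0

    def __post_init__(self):
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be > 0")
        if not 0.0 <= self.spatial_correlation_threshold <= 1.0:
            raise ValueError("spatial_correlation_threshold must be in [0, 1]")
        if self.noise_score_threshold < 0:
            raise ValueError("noise_score_threshold must be >= 0")
        gx, gy = self.quadrat_grid
        if gx * gy < 2:
            raise ValueError("quadrat_grid must have >= 2 cells")
        w = self.score_weights
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("score_weights must be >= 0 and sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        for key in ("quadrat_grid", "score_weights"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
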