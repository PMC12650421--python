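"""QC: background consistency, tissue classification, CSR noise scoring."""

import numpy as np
import pytest

from spatmet.matrix import FeatureMatrix, ValidationError
from spatmet.params import AnalysisParams
from spatmet.qc import (MAX_NOISE_SCORE, background_consistency, classify_pixels,
                        filter_noise, intensity_summaries, missing_stats, noise_scores,
                        tissue_enriched_ions)
from spatmet.regions import RegionMask


def _grid_fm(w, h, intensities):
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    inten = np.asarray(intensities, dtype=float)
    mz = 100.0 + np.arange(inten.shape[1])
    return FeatureMatrix(coords, mz, inten)


# ------------------------------------------------------------- QC1

def test_background_identical_regions_r_one(tiny_fm):
    a = RegionMask("background-1", [0, 1])
    b = RegionMask("background-2", [0, 1])
    rep = background_consistency(tiny_fm, [a, b])
    assert rep.correlation.iloc[0, 1] == pytest.approx(1.0)


def test_background_scaled_spectrum_r_one():
    # region B's pixels carry exactly 3x region A's spectrum: Pearson r = 1
    inten = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                      [3.0, 6.0, 9.0], [3.0, 6.0, 9.0]])
    fm = _grid_fm(2, 2, inten)
    rep = background_consistency(fm, [RegionMask("background-1", [0, 1]),
                                      RegionMask("background-2", [2, 3])])
    assert rep.correlation.iloc[0, 1] == pytest.approx(1.0)


def test_background_matches_covariance_formula(demo):
    fm, truth = demo
    bg = np.setdiff1d(np.arange(fm.n_pixels), truth.tissue_pixels)
    a, b = RegionMask("background-1", bg[:200]), RegionMask("background-2", bg[200:400])
    rep = background_consistency(fm, [a, b])
    sa = fm.intensities[a.pixel_indices].mean(axis=0)
    sb = fm.intensities[b.pixel_indices].mean(axis=0)
    expected = ((sa - sa.mean()) * (sb - sb.mean())).sum() / np.sqrt(
        ((sa - sa.mean()) ** 2).sum() * ((sb - sb.mean()) ** 2).sum()
    )
    assert rep.correlation.iloc[0, 1] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_region_gives_nan():
    inten = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
    fm = _grid_fm(2, 2, inten)
    with pytest.warns(UserWarning, match="zero-variance"):
        rep = background_consistency(fm, [RegionMask("background-1", [0, 1]),
                                          RegionMask("background-2", [2, 3])])
    assert np.isnan(rep.correlation.iloc[0, 1])


# ---------------------------------------------- tissue enrichment

def test_enrichment_strict_inequality():
    inten = np.array([[10.0, 5.0, 7.0], [10.0, 5.0, 7.0],
                      [5.0, 5.0, 0.0], [5.0, 5.0, 0.0]])
    fm = _grid_fm(2, 2, inten)
    enr = tissue_enriched_ions(fm, RegionMask("t", [0, 1]), RegionMask("b", [2, 3]))
    # ion 0: 10 vs 5 -> in; ion 1: equal means -> out; ion 2: bg mean 0, tissue > 0 -> in
    assert list(enr) == [0, 2]


def test_enrichment_recovers_planted_tissue_ions(demo):
    fm, truth = demo
    bg = np.setdiff1d(np.arange(fm.n_pixels), truth.tissue_pixels)
    enr = tissue_enriched_ions(fm, RegionMask("t", truth.tissue_pixels),
                               RegionMask("b", bg))
    recall = np.isin(truth.structured_ions, enr).mean()
    assert recall == 1.0


def test_classify_threshold_below_min_keeps_all(tiny_fm):
    tissue, background = classify_pixels(tiny_fm, np.array([0, 1]), 1e-6)
    assert len(tissue) == tiny_fm.n_pixels and len(background) == 0


def test_classify_is_monotone_in_threshold(demo):
    fm, truth = demo
    enr = truth.structured_ions
    sizes = []
    for thr in [1e2, 1e4, truth.separating_threshold, 1e7]:
        t, _ = classify_pixels(fm, enr, thr)
        sizes.append(len(t))
    assert sizes == sorted(sizes, reverse=True)


def test_classify_recovers_planted_mask(demo):
    fm, truth = demo
    tissue, background = classify_pixels(fm, truth.structured_ions,
                                         truth.separating_threshold)
    true = np.zeros(fm.n_pixels, bool)
    true[truth.tissue_pixels] = True
    pred = np.zeros(fm.n_pixels, bool)
    pred[tissue.pixel_indices] = True
    assert (pred == true).mean() >= 0.98


def test_classify_empty_tissue_is_error(tiny_fm):
    with pytest.raises(ValidationError):
        classify_pixels(tiny_fm, np.array([0, 1]), 1e12)


# ------------------------------------------------ CSR quadrat test

def test_quadrat_statistic_hand_example():
    """100 detections in one of 4 equal quadrats: X2 = 75^2/25 + 3*25 = 300."""
    w = h = 20  # 4 quadrats of 10x10 = 100 pixels each
    inten = np.zeros((w * h, 1))
    fm = _grid_fm(w, h, inten)
    # all 100 detections fill the upper-left 10x10 quadrat
    sel = (fm.coords[:, 0] < 10) & (fm.coords[:, 1] < 10)
    fm.intensities[sel, 0] = 1.0
    tissue = RegionMask("t", np.arange(w * h))
    tab = noise_scores(fm, tissue, grid=(2, 2))
    assert tab["statistic"][0] == pytest.approx(300.0)
    assert tab["df"][0] == 3


def test_uniform_detection_scores_near_zero():
    fm = _grid_fm(16, 16, np.ones((256, 1)))
    tab = noise_scores(fm, RegionMask("t", np.arange(256)))
    assert tab["statistic"][0] == pytest.approx(0.0)
    assert tab["noise_score"][0] == 0.0  # saturated pattern: no information
    assert bool(tab["degenerate"][0])


def test_zero_detection_ion_flagged_score_zero():
    fm = _grid_fm(8, 8, np.zeros((64, 1)))
    tab = noise_scores(fm, RegionMask("t", np.arange(64)))
    assert tab["noise_score"][0] == 0.0
    assert bool(tab["degenerate"][0])


def test_score_invariant_to_intensity_rescaling(demo_filtered):
    fm, tissue = demo_filtered["fm"], demo_filtered["tissue"]
    t1 = noise_scores(fm, tissue)
    fm2 = FeatureMatrix(fm.coords, fm.mz, fm.intensities * 37.5)
    t2 = noise_scores(fm2, tissue)
    np.testing.assert_allclose(t1["noise_score"], t2["noise_score"])


def test_score_capped_at_300(demo_filtered):
    table = demo_filtered["table"]
    assert (table["noise_score"] <= MAX_NOISE_SCORE).all()
    assert (table["noise_score"] >= 0).all()


def test_filter_threshold_zero_is_identity(demo_filtered):
    fm_tissue, table = demo_filtered["fm_tissue"], demo_filtered["table"]
    out = filter_noise(fm_tissue, table, 0.0)
    assert out.n_ions == fm_tissue.n_ions


def test_filter_removing_everything_is_error(demo_filtered):
    with pytest.raises(ValidationError):
        filter_noise(demo_filtered["fm_tissue"], demo_filtered["table"],
                     MAX_NOISE_SCORE + 1)


def test_filter_recovers_planted_structured_set(demo_filtered):
    truth, table = demo_filtered["truth"], demo_filtered["table"]
    keep = demo_filtered["keep"]
    is_noise = np.zeros(len(table), bool)
    is_noise[truth.noise_ions] = True
    precision = (~is_noise[keep]).mean()
    recall = np.isin(truth.structured_ions, keep).mean()
    assert precision >= 0.95 and recall >= 0.95


# --------------------------------------------------------- QC2/QC3

def test_constant_matrix_medians():
    fm = _grid_fm(3, 3, np.full((9, 4), 2.5))
    pix, ion = intensity_summaries(fm)
    assert np.allclose(pix, 2.5) and np.allclose(ion, 2.5)


def test_single_ion_pixel_map_equals_image(tiny_fm):
    one = tiny_fm.subset_ions([0])
    pix, ion = intensity_summaries(one)
    np.testing.assert_allclose(pix, one.intensities[:, 0])


def test_median_matches_sort_oracle():
    rng = np.random.default_rng(3)
    inten = rng.uniform(0, 10, (16, 7))
    inten[rng.random((16, 7)) < 0.3] = 0.0
    inten[:, 0] = np.maximum(inten[:, 0], 0.1)  # keep every pixel detectable
    fm = _grid_fm(4, 4, inten)
    pix, ion = intensity_summaries(fm)
    for i in range(16):
        vals = sorted(v for v in inten[i] if v > 0)
        assert pix[i] == pytest.approx(np.median(vals))


def test_missingness_bounds_and_identity(demo):
    fm, _ = demo
    rep = missing_stats(fm)
    assert rep.pixel_missing_ratio.min() >= 0 and rep.pixel_missing_ratio.max() <= 1
    # mean over pixels == overall zero fraction == mean over ions
    overall = (fm.intensities == 0).mean()
    assert rep.pixel_missing_ratio.mean() == pytest.approx(overall)
    assert rep.ion_missing_ratio.mean() == pytest.approx(overall)


def test_missingness_extremes():
    fm = _grid_fm(2, 2, np.ones((4, 2)))
    rep = missing_stats(fm)
    assert np.all(rep.pixel_missing_ratio == 0) and np.all(rep.ion_missing_ratio == 0)
    fm0 = _grid_fm(2, 2, np.zeros((4, 2)))
    rep0 = missing_stats(fm0)
    assert np.all(rep0.pixel_missing_ratio == 1) and np.all(rep0.ion_missing_ratio == 1)


def test_dropout_matches_binomial_expectation(demo):
    """Noise-ion missingness: detection prob 0.3 -> missing ratio near 0.7."""
    fm, truth = demo
    rep = missing_stats(fm)
    p_missing = 1 - truth.spec.noise_detect * (1 - truth.spec.dropout)
    got = rep.ion_missing_ratio[truth.noise_ions].mean()
    se = np.sqrt(p_missing * (1 - p_missing) / (fm.n_pixels * len(truth.noise_ions)))
    assert abs(got - p_missing) < 3 * se + 1e-3
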