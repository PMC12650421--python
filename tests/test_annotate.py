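"""Isotope/adduct detection, database matching and composite scoring."""

import numpy as np
import pytest

from spatmet.adducts import BUILTIN_ADDUCTS, get_adducts
from spatmet.annotate import (AnnotationCandidate, annotation_summary, find_adduct_pairs,
                              find_isotope_pairs, ion_roles, match_database,
                              remove_isotopic_peaks, score_annotations)
from spatmet.library import MetaboliteLibrary, MetaboliteRecord
from spatmet.matrix import FeatureMatrix
from spatmet.params import AnalysisParams


@pytest.fixture(scope="module")
def detected(demo_filtered):
    """Isotope and adduct pairs detected on the filtered demo matrix."""
    fm = demo_filtered["fm_filtered"]
    iso = find_isotope_pairs(fm)
    fm_mono = remove_isotopic_peaks(fm, iso)
    keep_mono = np.setdiff1d(np.arange(fm.n_ions),
                             np.array(sorted({p.iso_ion for p in iso}), dtype=int))
    add = find_adduct_pairs(fm_mono, get_adducts())
    return {"iso": iso, "add": add, "fm_mono": fm_mono, "keep_mono": keep_mono}


def _orig_pairs(pairs, orig_of, kind):
    if kind == "iso":
        return {(orig_of[p.mono_ion], orig_of[p.iso_ion]) for p in pairs}
    return {(orig_of[p.ion_a], orig_of[p.ion_b]) for p in pairs}


def test_isotope_pairs_recovered(demo_filtered, detected):
    truth, orig_of = demo_filtered["truth"], demo_filtered["orig_of"]
    pred = _orig_pairs(detected["iso"], orig_of, "iso")
    want = {(m, i) for m, i, _, _ in truth.isotope_pairs}
    tp = len(pred & want)
    assert tp / max(len(pred), 1) >= 0.9    # precision
    assert tp / len(want) >= 0.9            # recall


def test_adduct_pairs_recovered(demo_filtered, detected):
    truth = demo_filtered["truth"]
    orig_of = demo_filtered["orig_of"]
    omap = {new: orig_of[o] for new, o in enumerate(detected["keep_mono"])}
    pred = _orig_pairs(detected["add"], omap, "add")
    want = {(a, b) for a, b, _, _, _ in truth.adduct_pairs}
    tp = len(pred & want)
    assert tp / max(len(pred), 1) >= 0.9
    assert tp / len(want) >= 0.9


def test_confirmed_pairs_meet_spatial_threshold(detected):
    rho = AnalysisParams().spatial_correlation_threshold
    assert all(p.moran_i >= rho for p in detected["iso"])
    assert all(p.moran_i >= rho for p in detected["add"])


def test_wrong_spacing_never_a_candidate():
    """Two perfectly correlated ions 50 ppm off the isotope spacing: no pair."""
    rng = np.random.default_rng(0)
    xs, ys = np.meshgrid(np.arange(10), np.arange(10))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    img = np.exp(-((coords[:, 0] - 5) ** 2 + (coords[:, 1] - 5) ** 2) / 8.0) * 1000
    m0 = 300.0
    bad_delta = 1.0033548 * (1 + 50e-6 * 300)  # way outside 10 ppm at m/z 300
    fm = FeatureMatrix(coords, [m0, m0 + 2 * 1.0033548],
                       np.column_stack([img, img * 0.05]))
    pairs = find_isotope_pairs(fm)
    assert pairs == []


def test_implausibly_bright_companion_rejected():
    """Correct spacing but iso/mono ratio above any credible carbon count."""
    xs, ys = np.meshgrid(np.arange(10), np.arange(10))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    img = np.exp(-((coords[:, 0] - 5) ** 2 + (coords[:, 1] - 5) ** 2) / 8.0) * 1000
    fm = FeatureMatrix(coords, [150.0, 150.0 + 1.0033548],
                       np.column_stack([img, img * 0.9]))  # bound at 150: 0.011*12=0.13
    assert find_isotope_pairs(fm) == []


def test_remove_isotopic_peaks_idempotent(demo_filtered, detected):
    fm = demo_filtered["fm_filtered"]
    once = remove_isotopic_peaks(fm, detected["iso"])
    assert once.n_ions == fm.n_ions - len({p.iso_ion for p in detected["iso"]})
    again = remove_isotopic_peaks(once, [])
    assert again.n_ions == once.n_ions


def test_ion_roles_partition(demo_filtered, detected):
    roles = ion_roles(demo_filtered["fm_filtered"], detected["iso"])
    assert set(roles) <= {"monoisotopic", "isotopic", "unpaired"}
    assert (roles == "isotopic").sum() == len({p.iso_ion for p in detected["iso"]})


# ------------------------------------------------- database matching

def _glucose_library():
    from spatmet.elements import parse_formula

    return MetaboliteLibrary([
        MetaboliteRecord(id="glc", name="glucose", neutral_monoisotopic_mass=180.063388,
                         formula=parse_formula("C6H12O6")),
    ])


def _toy_fm(mz_values):
    coords = [(0, 0), (1, 0), (0, 1), (1, 1)]
    inten = np.tile(np.array([[1.0, 2.0, 3.0, 4.0]]).T, (1, len(mz_values)))
    return FeatureMatrix(coords, mz_values, inten)


def test_single_ion_matches_glucose():
    fm = _toy_fm([181.070665])
    cands = match_database(fm, [], [], _glucose_library(), get_adducts(["[M+H]+"]))
    assert len(cands) == 1
    assert abs(cands[0].ppm_error) < 0.5
    assert cands[0].adduct == "[M+H]+" and not cands[0].adduct_evidence


def test_empty_adduct_list_no_candidates():
    fm = _toy_fm([181.070665])
    assert match_database(fm, [], [], _glucose_library(), []) == []


def test_infeasible_water_loss_never_matched():
    """A C7H3F5 record cannot be reached through [M+H-H2O]+."""
    from spatmet.elements import formula_monoisotopic_mass, parse_formula

    f = parse_formula("C7H3F5")
    mass = formula_monoisotopic_mass(f)
    lib = MetaboliteLibrary([MetaboliteRecord(id="x", name="C7H3F5",
                                              neutral_monoisotopic_mass=mass, formula=f)])
    adduct = BUILTIN_ADDUCTS["[M+H-H2O]+"]
    fm = _toy_fm([mass + adduct.mass_shift])
    cands = match_database(fm, [], [], lib, [adduct])
    assert cands == []


def test_empty_library_is_error():
    fm = _toy_fm([181.070665])
    with pytest.raises(ValueError):
        match_database(fm, [], [], MetaboliteLibrary([]), get_adducts())


def test_match_independent_of_library_order():
    from spatmet.elements import parse_formula

    recs = [
        MetaboliteRecord(id="a", name="a", neutral_monoisotopic_mass=180.0633,
                         formula=parse_formula("C6H12O6")),
        MetaboliteRecord(id="b", name="b", neutral_monoisotopic_mass=180.0640),
    ]
    fm = _toy_fm([181.070665])
    got1 = {c.record.id for c in match_database(fm, [], [], MetaboliteLibrary(recs),
                                                get_adducts(["[M+H]+"]))}
    got2 = {c.record.id for c in match_database(fm, [], [], MetaboliteLibrary(recs[::-1]),
                                                get_adducts(["[M+H]+"]))}
    assert got1 == got2 == {"a", "b"}


def test_pipeline_true_record_ranks_first(demo_filtered, detected):
    """Every planted metabolite ion gets a candidate; truth ranks first >= 90%."""
    truth, orig_of = demo_filtered["truth"], demo_filtered["orig_of"]
    fm = demo_filtered["fm_filtered"]
    cands = match_database(fm, detected["iso"],
                           [  # translate adduct pairs into fm's index space
                               type(p)(int(detected["keep_mono"][p.ion_a]),
                                       int(detected["keep_mono"][p.ion_b]),
                                       p.adduct_a, p.adduct_b, p.neutral_mass,
                                       p.ppm_error, p.moran_i)
                               for p in detected["add"]
                           ],
                           truth.library, get_adducts())
    cands = score_annotations(cands)
    best = {c.ion: c for c in cands if c.rank == 1}
    planted = [(new, truth.metabolite_of_ion[orig_of[new]])
               for new in range(fm.n_ions)
               if orig_of[new] in truth.metabolite_of_ion
               and orig_of[new] not in {i for _, i, _, _ in truth.isotope_pairs}]
    assert planted
    hits = [best[ion].record.id == met for ion, met in planted if ion in best]
    assert len(hits) / len(planted) >= 0.9          # candidate coverage
    assert np.mean(hits) >= 0.9                     # rank-1 correctness


# ----------------------------------------------------------- scoring

def _cand(ppm, iso, evidence):
    rec = MetaboliteRecord(id="r", name="r", neutral_monoisotopic_mass=100.0)
    return AnnotationCandidate(ion=0, mz=101.0, record=rec, adduct="[M+H]+",
                               adduct_evidence=evidence, ppm_error=ppm,
                               isotope_similarity=iso)


def test_score_maximum():
    c = _cand(0.0, 1.0, True)
    score_annotations([c])
    assert c.score == pytest.approx(1.0)


def test_score_minimum():
    c = _cand(10.0, None, False)  # |ppm| == tolerance, no iso, no adduct
    score_annotations([c])
    assert c.score == pytest.approx(0.0)


def test_score_worked_example():
    """Default weights (0.5, 0.3, 0.2): ppm = tol/2, iso 0.8, adduct yes -> 0.69."""
    c = _cand(5.0, 0.8, True)
    score_annotations([c])
    assert c.score == pytest.approx(0.25 + 0.24 + 0.2)


def test_missing_iso_weight_redistributes():
    c = _cand(0.0, None, True)  # (0.5*1 + 0.2*1) / 0.7 = 1.0
    score_annotations([c])
    assert c.score == pytest.approx(1.0)


def test_ranking_sorted_by_score_then_ppm():
    cands = [_cand(8.0, None, False), _cand(2.0, None, False), _cand(-2.0, None, False)]
    score_annotations(cands)
    ranks = sorted((c.rank, abs(c.ppm_error)) for c in cands)
    assert [r for r, _ in ranks] == [1, 2, 3]
    assert ranks[0][1] <= ranks[2][1]


# ----------------------------------------------------------- summary

def test_summary_histogram():
    recs = [MetaboliteRecord(id=str(i), name=str(i), neutral_monoisotopic_mass=100.0 + i)
            for i in range(8)]

    def mk(ion, n):
        return [AnnotationCandidate(ion=ion, mz=200.0 + ion, record=recs[k],
                                    adduct="[M+H]+", adduct_evidence=False,
                                    ppm_error=0.0) for k in range(n)]

    cands = mk(0, 1) + mk(1, 2) + mk(2, 5)
    s = annotation_summary(cands, total_ions=10)
    assert s.histogram == {"1": 1, "2": 1, "3+": 1}
    assert s.n_annotated == 3 and s.fraction_annotated == 0.3
    assert sum(s.histogram.values()) == s.n_annotated
    assert len(s.multi_match_mz) == 2


def test_summary_empty():
    s = annotation_summary([], total_ions=5)
    assert s.n_annotated == 0 and s.histogram == {"1": 0, "2": 0, "3+": 0}
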