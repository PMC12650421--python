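"""Synthetic spatial-metabolomics generator with planted ground truth.

The generator emulates the statistical structure a downstream imaging
workflow assumes:

* a tissue area (ellipse) on a rectangular slide, divided into
  sub-regions with distinct metabolic programs;
* structured ions confined to one sub-region: intensity follows a
  smooth spatial program (a Gaussian bump on a within-region floor)
  times a smooth log-normal abundance field, with iid log-normal pixel
  noise, and pixels are "detected" where the signal clears a relative
  detection limit (missingness tracks abundance, as in real data);
* noise ions detected uniformly at random over the whole slide
  (complete spatial randomness), carrying no spatial information;
* isotopologue companions at +1.003355 Da with the chemically expected
  intensity ratio (1.1% per carbon atom of the generating formula),
  sharing the parent's spatial field and detection support;
* adduct families: several charged forms of one neutral metabolite at
  the corresponding m/z shifts, sharing one abundance field;
* differentially abundant ions detected tissue-wide whose intensity and
  detection rate are elevated in one region;
* a faint background baseline so that total intensity over
  tissue-enriched ions separates tissue from background pixels.

All randomness flows from one seed through named substreams, so adding
ions of one class does not perturb another class's draws.  Planted m/z
values are rejection-sampled to keep unrelated ions at least 20 ppm
away from every isotope/adduct spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .adducts import BUILTIN_ADDUCTS, mz_from_neutral
from .elements import formula_monoisotopic_mass, parse_formula
from .library import MetaboliteLibrary, MetaboliteRecord
from .matrix import FeatureMatrix

C13_DELTA = 1.0033548352

#: Small-molecule formulas used to plant annotatable ions (common tissue
#: metabolites; masses derived from the bundled isotope table).
PLANTED_METABOLITES: list[tuple[str, str]] = [
    ("glucose", "C6H12O6"),
    ("glutamate", "C5H9NO4"),
    ("glutamine", "C5H10N2O3"),
    ("citrate", "C6H8O7"),
    ("taurine", "C2H7NO3S"),
    ("creatine", "C4H9N3O2"),
    ("carnitine", "C7H15NO3"),
    ("adenosine", "C10H13N5O4"),
    ("inosine", "C10H12N4O5"),
    ("glutathione", "C10H17N3O6S"),
    ("AMP", "C10H14N5O7P"),
    ("tryptophan", "C11H12N2O2"),
    ("tyrosine", "C9H11NO3"),
    ("phenylalanine", "C9H11NO2"),
    ("arginine", "C6H14N4O2"),
    ("histidine", "C6H9N3O2"),
    ("lysine", "C6H14N2O2"),
    ("methionine", "C5H11NO2S"),
    ("sucrose", "C12H22O11"),
    ("glucose-6-phosphate", "C6H13O9P"),
    ("palmitate", "C16H32O2"),
    ("stearate", "C18H36O2"),
    ("oleate", "C18H34O2"),
    ("arachidonate", "C20H32O2"),
    ("LPC 16:0", "C24H50NO7P"),
    ("PC 34:1", "C42H82NO8P"),
    ("SM d18:1/16:0", "C39H79N2O6P"),
    ("cholesterol", "C27H46O"),
    ("serotonin", "C10H12N2O"),
    ("dopamine", "C8H11NO2"),
    ("GABA", "C4H9NO2"),
    ("hypoxanthine", "C5H4N4O"),
    ("guanine", "C5H5N5O"),
    ("proline", "C5H9NO2"),
    ("threonine", "C4H9NO3"),
    ("asparagine", "C4H8N2O3"),
]

#: Relative amplitudes of adduct forms within a planted family.
ADDUCT_AMPLITUDES = {
    "[M+H]+": 1.0,
    "[M+Na]+": 0.55,
    "[M+K]+": 0.35,
    "[M+NH4]+": 0.45,
    "[M+H-H2O]+": 0.30,
}


@dataclass
class SimulationSpec:
    width: int = 60
    height: int = 60
    n_regions: int = 3
    n_structured: int = 120
    n_noise: int = 80
    n_isotope_pairs: int = 20
    n_adduct_families: int = 10
    n_de: int = 30
    de_fold_change: float = 2.0
    intensity_scale: float = 1e5
    pixel_noise_sigma: float = 0.3    # iid per-pixel log-normal sigma
    field_noise_sigma: float = 0.4    # smooth shared abundance-field sigma (log scale)
    field_smooth_sigma: float = 3.0   # spatial correlation length of the field (pixels)
    region_floor: float = 0.3         # program level at region edges
    bump_sigma: float = 10.0          # Gaussian bump width (pixels)
    detect_max: float = 0.95          # detection prob where signal clears the limit
    detect_cut: float = 0.1           # relative detection limit for structured ions
    de_detect_cut: float = 1.0        # relative detection limit for DE ions
    de_detect_case: float = 0.95      # DE thinning inside the elevated region
    de_detect_rest: float = 0.35      # ... and elsewhere in tissue
    dropout: float = 0.05             # extra random zeroing of detected cells
    background_detect: float = 0.02
    background_scale: float = 200.0
    noise_detect: float = 0.3
    noise_scale: float = 500.0
    mz_min: float = 120.0
    mz_max: float = 950.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_structured, self.n_noise, self.n_isotope_pairs,
               self.n_adduct_families, self.n_de) < 0:
            raise ValueError("ion counts must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.de_fold_change <= 0:
            raise ValueError("fold changes must be > 0")
        n_met = self.n_isotope_pairs + self.n_adduct_families
        if n_met > len(PLANTED_METABOLITES):
            raise ValueError(
                f"at most {len(PLANTED_METABOLITES)} metabolite-backed ion groups supported"
            )


@dataclass
class SyntheticTruth:
    spec: SimulationSpec
    tissue_pixels: np.ndarray          # row indices of tissue pixels
    region_of_pixel: np.ndarray        # per row: region id 0..R-1, -1 off tissue
    noise_ions: np.ndarray
    structured_ions: np.ndarray        # every non-noise ion
    isotope_pairs: list                # (mono, iso, expected_ratio, n_carbon)
    adduct_pairs: list                 # (ion_a, ion_b, adduct_a, adduct_b, neutral_mass)
    adduct_of_ion: dict                # ion -> (adduct name, metabolite id)
    de_ions: list                      # (ion, region, direction)
    ion_region: dict                   # ion -> program region (pattern-bearing ions)
    library: MetaboliteLibrary
    metabolite_of_ion: dict            # ion -> metabolite id
    separating_threshold: float


_RELATION_DELTAS = None


def _relation_deltas() -> np.ndarray:
    global _RELATION_DELTAS
    if _RELATION_DELTAS is None:
        shifts = [a.mass_shift for a in BUILTIN_ADDUCTS.values()]
        deltas = {0.0, C13_DELTA, 2 * C13_DELTA}
        for i, si in enumerate(shifts):
            for sj in shifts[i + 1:]:
                deltas.add(abs(si - sj))
        _RELATION_DELTAS = np.array(sorted(deltas))
    return _RELATION_DELTAS


def _clashes(mz: float, existing: np.ndarray, ppm: float = 20.0) -> bool:
    """Would this m/z sit within 20 ppm of a relationship spacing to any existing ion?"""
    if existing.size == 0:
        return False
    gaps = np.abs(np.abs(existing - mz)[:, None] - _relation_deltas()[None, :])
    return bool((gaps <= mz * ppm * 1e-6).any())


def default_demo_spec() -> SimulationSpec:
    """The documented small demonstration scenario.

    60 x 60 slide, elliptical tissue with 3 regions, 120 structured
    ions, 80 CSR noise ions, 20 isotope pairs, 10 adduct families and
    30 differential ions.  Deterministic: repeated calls are equal.
    """
    return SimulationSpec()


def simulate_dataset(spec: SimulationSpec | None = None,
                     seed: int | None = None) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Generate a feature matrix plus its ground truth, reproducibly from a seed."""
    spec = spec or default_demo_spec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    names = ["geometry", "mz", "amplitude", "structured", "noise",
             "isotope", "adduct", "de", "background", "dropout"]
    children = np.random.SeedSequence(spec.seed).spawn(len(names))
    rng = {n: np.random.default_rng(c) for n, c in zip(names, children)}

    # ---- geometry ---------------------------------------------------
    w, h = spec.width, spec.height
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    coords = np.column_stack([xs.ravel(), ys.ravel()])  # row index = y*w + x
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rx, ry = 0.42 * w, 0.40 * h
    tissue_mask = (((coords[:, 0] - cx) / rx) ** 2 + ((coords[:, 1] - cy) / ry) ** 2) <= 1.0
    tissue_idx = np.flatnonzero(tissue_mask)
    if len(tissue_idx) < spec.n_regions:
        raise ValueError("more sub-regions than tissue pixels")
    phase = rng["geometry"].uniform(0, 2 * np.pi)
    angles = 2 * np.pi * np.arange(spec.n_regions) / spec.n_regions + phase
    centers = np.column_stack([cx + 0.5 * rx * np.cos(angles),
                               cy + 0.5 * ry * np.sin(angles)])
    d2 = ((coords[tissue_idx, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    region_t = d2.argmin(axis=1)
    region_of_pixel = np.full(len(coords), -1)
    region_of_pixel[tissue_idx] = region_t

    # per-region spatial program over tissue pixels
    programs = np.zeros((spec.n_regions, len(tissue_idx)))
    for r in range(spec.n_regions):
        inside = region_t == r
        bump = np.exp(-d2[:, r] / (2 * spec.bump_sigma ** 2))
        programs[r, inside] = spec.region_floor + (1 - spec.region_floor) * bump[inside]

    nt = len(tissue_idx)

    def smooth_field(stream) -> np.ndarray:
        """Smooth log-normal abundance field evaluated at the tissue pixels."""
        z = gaussian_filter(stream.normal(0.0, 1.0, (h, w)),
                            spec.field_smooth_sigma, mode="nearest")
        z = z / z.std() * spec.field_noise_sigma
        return np.exp(z.ravel()[tissue_idx])

    # ---- ion roster -------------------------------------------------
    mets = [
        (name, parse_formula(f), formula_monoisotopic_mass(parse_formula(f)))
        for name, f in PLANTED_METABOLITES
    ]
    proton = BUILTIN_ADDUCTS["[M+H]+"]
    ions: list[dict] = []
    mz_list: list[float] = []

    def add_ion(mz, **kw):
        ions.append({"mz": mz, **kw})
        mz_list.append(mz)

    used = 0
    iso_groups, family_groups = [], []
    for name, formula, mass in mets:
        if len(iso_groups) < spec.n_isotope_pairs:
            mz_mono = mz_from_neutral(mass, proton)
            if _clashes(mz_mono, np.asarray(mz_list)):
                continue
            iso_groups.append(name)
            add_ion(mz_mono, cls="iso_mono", met=name, formula=formula,
                    region=used % spec.n_regions, adduct="[M+H]+")
            add_ion(mz_mono + C13_DELTA, cls="iso_peak", met=name, formula=formula,
                    region=used % spec.n_regions)
            used += 1
        elif len(family_groups) < spec.n_adduct_families:
            forms = ["[M+H]+", "[M+Na]+"] if len(family_groups) % 2 == 0 else \
                    ["[M+H]+", "[M+Na]+", "[M+K]+"]
            mzs = [mz_from_neutral(mass, BUILTIN_ADDUCTS[f]) for f in forms]
            if any(_clashes(m, np.asarray(mz_list)) for m in mzs):
                continue
            family_groups.append(name)
            fam = len(family_groups) - 1
            for f, m in zip(forms, mzs):
                add_ion(m, cls="adduct", met=name, formula=formula,
                        region=used % spec.n_regions, adduct=f, family=fam,
                        neutral_mass=mass)
            used += 1
        else:
            break
    if len(iso_groups) < spec.n_isotope_pairs or len(family_groups) < spec.n_adduct_families:
        raise ValueError("could not place the requested metabolite-backed ion groups")

    def draw_free_mz(stream) -> float:
        for _ in range(10000):
            m = stream.uniform(spec.mz_min, spec.mz_max)
            if not _clashes(m, np.asarray(mz_list)):
                return m
        raise RuntimeError("m/z rejection sampling failed")

    for i in range(spec.n_structured):
        add_ion(draw_free_mz(rng["mz"]), cls="structured", region=i % spec.n_regions)
    for i in range(spec.n_de):
        add_ion(draw_free_mz(rng["mz"]), cls="de", region=i % spec.n_regions,
                direction="up")
    for i in range(spec.n_noise):
        add_ion(draw_free_mz(rng["mz"]), cls="noise")

    # ---- intensities ------------------------------------------------
    n_pix, n_ion = len(coords), len(ions)
    X = np.zeros((n_pix, n_ion))
    amp = rng["amplitude"]
    field_cache: dict = {}

    def family_field(key, stream) -> np.ndarray:
        if key not in field_cache:
            field_cache[key] = smooth_field(stream)
        return field_cache[key]

    def lognorm(stream, sigma, size):
        return np.exp(stream.normal(0.0, sigma, size))

    mono_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for j, ion in enumerate(ions):
        c = ion["cls"]
        if c == "noise":
            mask = rng["noise"].random(n_pix) < spec.noise_detect
            X[mask, j] = spec.noise_scale * lognorm(rng["noise"], 1.0, int(mask.sum()))
            continue
        if c == "de":
            r = ion["region"]
            in_r = region_t == r
            fld = smooth_field(rng["de"])
            v = fld * lognorm(rng["de"], spec.pixel_noise_sigma, nt)
            v[in_r] *= spec.de_fold_change
            p_keep = np.where(in_r, spec.de_detect_case, spec.de_detect_rest)
            det = (v > spec.de_detect_cut) & (rng["de"].random(nt) < p_keep)
            a = spec.intensity_scale * lognorm(amp, 0.5, 1)[0]
            X[tissue_idx[det], j] = a * v[det]
            continue
        r = ion["region"]
        stream_name = {"structured": "structured", "iso_mono": "isotope",
                       "iso_peak": "isotope", "adduct": "adduct"}[c]
        stream = rng[stream_name]
        if c == "iso_peak":
            v, det = mono_state[j - 1]
            n_c = ion["formula"].get("C", 0)
            ratio = 0.011 * n_c
            det_iso = det & (stream.random(nt) < 0.97)
            iso_v = ratio * v * lognorm(stream, 0.05, nt)
            X[tissue_idx[det_iso], j] = iso_v[det_iso]
            ion["expected_ratio"] = ratio
            continue
        if c == "structured":
            key = ("s", j)
        elif c == "iso_mono":
            key = ("i", ion["met"])
        else:
            key = ("a", ion["family"])
        fld = family_field(key, stream)
        g = programs[r]
        rel = g * fld * lognorm(stream, spec.pixel_noise_sigma, nt)
        det = (rel > spec.detect_cut) & (stream.random(nt) < spec.detect_max)
        a_sigma = 0.4 if c == "adduct" else 0.7
        a = spec.intensity_scale * lognorm(amp, a_sigma, 1)[0]
        if c == "adduct":
            a *= ADDUCT_AMPLITUDES[ion["adduct"]]
        v = a * rel
        X[tissue_idx[det], j] = v[det]
        if c == "iso_mono":
            mono_state[j] = (v, det)

    # faint background baseline on non-noise ions
    bg_idx = np.flatnonzero(~tissue_mask)
    for j, ion in enumerate(ions):
        if ion["cls"] == "noise":
            continue
        mask = rng["background"].random(len(bg_idx)) < spec.background_detect
        X[bg_idx[mask], j] = spec.background_scale * lognorm(
            rng["background"], 1.0, int(mask.sum())
        )

    if spec.dropout > 0:
        X[rng["dropout"].random(X.shape) < spec.dropout] = 0.0

    # ---- canonical column order & truth -----------------------------
    order = np.argsort(mz_list)
    inv = np.empty(n_ion, dtype=int)
    inv[order] = np.arange(n_ion)
    fm = FeatureMatrix(coords, np.asarray(mz_list)[order], X[:, order])

    noise_ions = np.array(sorted(inv[j] for j, d in enumerate(ions) if d["cls"] == "noise"),
                          dtype=int)
    structured_ions = np.setdiff1d(np.arange(n_ion), noise_ions)
    isotope_pairs = [
        (int(inv[j - 1]), int(inv[j]), d["expected_ratio"], d["formula"].get("C", 0))
        for j, d in enumerate(ions) if d["cls"] == "iso_peak"
    ]
    by_family: dict[int, list[int]] = {}
    for j, d in enumerate(ions):
        if d["cls"] == "adduct":
            by_family.setdefault(d["family"], []).append(j)
    adduct_pairs = []
    for members in by_family.values():
        members = sorted(members, key=lambda j: ions[j]["mz"])
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                ja, jb = members[a_i], members[b_i]
                adduct_pairs.append(
                    (int(inv[ja]), int(inv[jb]), ions[ja]["adduct"], ions[jb]["adduct"],
                     ions[ja]["neutral_mass"])
                )
    adduct_of_ion = {
        int(inv[j]): (d["adduct"], d["met"])
        for j, d in enumerate(ions) if d["cls"] in ("adduct", "iso_mono")
    }
    de_ions = [(int(inv[j]), d["region"], d["direction"])
               for j, d in enumerate(ions) if d["cls"] == "de"]
    ion_region = {int(inv[j]): d["region"] for j, d in enumerate(ions)
                  if d["cls"] in ("structured", "iso_mono", "iso_peak", "adduct")}
    metabolite_of_ion = {int(inv[j]): d["met"] for j, d in enumerate(ions) if "met" in d}

    library = MetaboliteLibrary(
        [MetaboliteRecord(id=name, name=name, neutral_monoisotopic_mass=mass, formula=formula)
         for name, formula, mass in mets],
        provenance="synthetic",
    )

    totals = fm.intensities[:, structured_ions].sum(axis=1)
    t_min = totals[tissue_idx].min()
    b_max = totals[bg_idx].max() if len(bg_idx) else 0.0
    if b_max <= 0:
        threshold = t_min / 10 if t_min > 0 else 1.0
    else:
        threshold = float(np.sqrt(max(t_min, 1e-12) * b_max))

    truth = SyntheticTruth(
        spec=spec,
        tissue_pixels=tissue_idx,
        region_of_pixel=region_of_pixel,
        noise_ions=noise_ions,
        structured_ions=structured_ions,
        isotope_pairs=isotope_pairs,
        adduct_pairs=adduct_pairs,
        adduct_of_ion=adduct_of_ion,
        de_ions=de_ions,
        ion_region=ion_region,
        library=library,
        metabolite_of_ion=metabolite_of_ion,
        separating_threshold=threshold,
    )
    return fm, truth
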