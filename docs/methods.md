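# Methods

`spatmet` implements the downstream half of a mass spectrometry imaging
(MSI) experiment: it starts from a pixel-by-ion feature matrix (peak
picking and alignment are upstream concerns) and ends with annotated,
spatially organized, differentially tested metabolite ions.  This note
records the models and procedures, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## Data model

A `FeatureMatrix` holds integer pixel coordinates, a strictly
increasing m/z list, and a non-negative intensity matrix.  Zero means
"not detected"; grid cells with no row at all (e.g. background pixels
removed during preprocessing) are *off-slide*, a distinct state that
propagates into image exports as NaN.  Intensity zero and "missing" are
treated as synonymous throughout (missingness statistics count zeros),
because the input format carries no separate missing marker.

## Quality control

**Background consistency (QC1).**  Mean spectra of two or more
user-delimited background areas are compared with Pearson correlation.
On a stable acquisition, background areas differ only by noise, so r
should be near 1; low r flags contamination or drift.

**Tissue/background classification.**  Ions enriched in tissue
(mean(tissue)/mean(background) > 1, strict) define a per-pixel total
intensity; a threshold splits pixels into tissue and removable
background.  The threshold is the user's choice; an Otsu proposal on
log-total intensity is offered as a starting point.  Classification is
monotone in the threshold.

**Noise-ion scoring.**  For each ion, the tissue pixels where it is
detected form a point pattern.  Under the null of complete spatial
randomness (CSR) the pattern carries no anatomical information, so
CSR-compatible ions are filtered.  The test is a quadrat chi-square:
the tissue bounding box is cut into an 8x8 grid (configurable), empty
quadrats are dropped, expected counts are proportional to each
quadrat's tissue-pixel count, and the grid is coarsened per ion until
the mean expected count is at least 1.  The noise score is
-log10(p), floored at p = 1e-300 (score cap 300); ions scoring below
the threshold (default 30) are removed.

Two deliberate choices here:

* *Presence, not intensity.*  The test uses detection presence
  (intensity > 0), the quadrat-count convention; intensity structure is
  assessed by the downstream pattern analyses instead.
* *Finite-population correction.*  Detections live on a lattice with at
  most one event per pixel, so quadrat counts given n detections are
  multivariate hypergeometric, not multinomial; their variance is
  deflated by (N - n)/(N - 1).  The Pearson statistic is divided by
  this factor before the chi-square tail is evaluated.  Without it, an
  ion detected on 30% of the tissue has systematically small statistics
  and the two-sided p-values pile up near zero; with it, simulated CSR
  p-values are uniform to KS distance < 0.05 at 500 ions.  The reported
  `statistic` column keeps the uncorrected Pearson value.

The p-value is two-sided (smaller tail doubled, capped at 1):
significant regularity, not only clustering, departs from CSR.  Two
degenerate patterns carry no spatial information at all and are scored
0 and flagged: ions never detected in tissue, and saturated ions
detected at every tissue pixel (their counts match the expectation by
construction, not randomness).

**QC2/QC3.**  Median intensity per pixel and per ion (over detected
values only), and missing-value ratios per pixel and per ion.  The mean
pixel missing ratio, the mean ion missing ratio and the overall zero
fraction coincide by construction.

## Spatial correlation of ion pairs

Two peaks produced by one molecule (an isotopologue or another adduct
form) must light up the same structures.  This is quantified with
bivariate Moran's I over tissue pixels under row-standardized queen
(8-neighbor) grid weights:

    I_ab = (n / S0) * (z_a' W z_b + z_b' W z_a) / (2 sqrt((z_a'z_a)(z_b'z_b)))

with z mean-centered intensities and S0 the total weight.  Both
variables are standardized, so the statistic is invariant to either
ion's intensity scale, and the numerator is symmetrized because W is
not symmetric after row standardization.  (Normalizing by only one
variable's variance and averaging the two orientations — a form
sometimes written down for this statistic — is unbounded when the two
ions differ in scale, which isotopologue pairs always do; the
standardized form keeps test values in [-1.5, 1.5] on these grids, and
a rook-adjacency checkerboard against itself gives exactly -1.)
Confirmation threshold rho defaults to 0.5 for both isotope and adduct
pairs, exposed separately.

## Isotope and adduct identification

**Isotope pairs.**  Candidates are peak pairs separated by the +1
isotopologue spacing (13C - 12C = 1.003355 Da; charge 1 is the default
for small-molecule imaging, higher charge divides the spacing) within
the ppm tolerance (default 10).  A candidate must also be chemically
plausible: mean(iso)/mean(mono) <= 0.011 x floor(mz/12), i.e. no
brighter than the most carbon-rich molecule of that mass allows
(~1.1% abundance per 13C).  Survivors are confirmed at I >= rho; chains
(+2, +3, ...) grow from confirmed +1 peaks; an ion claimed by several
parents keeps the highest-I assignment.  Confirmed non-monoisotopic
peaks are removed before adduct detection.

**Adduct pairs.**  For each ion pair and each ordered pair of adduct
hypotheses from the user's list (defaults: [M+H]+, [M+Na]+, [M+K]+,
[M+NH4]+, [M+H-H2O]+), the pair is a candidate when the two implied
neutral masses (M = mz x z - shift, electron-mass aware) agree within
tolerance, and is confirmed at I >= rho.  Conflicting neutral-mass
interpretations of one ion are all kept and flagged, never merged.

**Database matching.**  Ions with a confirmed adduct form are matched
to the library by that single neutral mass; others try every adduct in
the list.  Matches whose formula cannot support the adduct (a water
loss requires an available oxygen, etc.) are discarded — an oxygen-free
molecule like C7H3F5 can never match through [M+H-H2O]+.  All
surviving candidates are retained for the user.

**Isotope-pattern evidence.**  For ions with a confirmed isotope chain,
the theoretical pattern of the matched formula (adduct applied) is
compared with the observed chain of tissue-mean intensities using
spectral-entropy similarity: with each spectrum normalized to unit
total intensity and S_a, S_b, S_ab the Shannon entropies of the two
spectra and their half-and-half merge, similarity =
1 - (2 S_ab - S_a - S_b)/ln 4, clamped to [0, 1].  Theoretical
patterns come from iterative convolution of per-element isotope
distributions (binary exponentiation per element), merging peaks
within 1e-4 Da and pruning below a relative floor (default 1e-3)
after each convolution; the element table (masses and abundances,
CODATA/NIST values) is vendored so results are reproducible offline.
The convolution agrees with exhaustive isotopologue enumeration to
1e-9 absolute abundance on all tested formulas up to 12 atoms.

**Composite score.**  score = w_mass (1 - |ppm|/tol) + w_iso iso_sim +
w_add 1{pair-confirmed adduct}, defaults (0.5, 0.3, 0.2).  The linear
form and the weights are this package's construction (configurable and
recorded in every output); when isotope similarity is unavailable its
weight is redistributed proportionally so the score stays on [0, 1].
Candidates are ranked per ion by score, ties broken by |ppm|.

## Pattern discovery

**Pixel dimension.**  Profiles are total-intensity normalized (median
size factor), log1p-transformed, z-scored per ion and reduced to 30
principal components (full SVD, fixed sign convention, deterministic).
Two methods: Louvain communities on a shared-nearest-neighbor graph
(k = 20, Jaccard weights, weak edges pruned below 1/15, resolution 1.0)
and k-means on a 2-D UMAP embedding (n_neighbors 30, min_dist 0.1).
"LM"/"SLM" method names map to Louvain with a logged notice.  Both are
deterministic under a fixed seed; clustering is invariant to global
intensity scaling.

**Ion dimension.**  Each ion image is normalized to unit sum, smoothed
with a 3x3 mean over observed pixels, and the resulting spatial
profiles are k-means clustered; each cluster's mean profile (scaled to
unit maximum) is the co-expression pattern.  This is a deliberately
simple, documented profile-clustering stand-in for specialized spatial
pattern tools; the interface isolates it so a different engine can be
dropped in.

## Differential analysis

Groups are pixel sets from cluster ids or rasterized ROI polygons
(case/control must be disjoint, each with at least 2 pixels).  Each ion
gets a two-sided Wilcoxon rank-sum test: exact enumeration when both
groups have <= 25 pixels and the pooled values are tie-free, otherwise
the normal approximation with tie correction.  A column of entirely
identical values is defined as p = 1.  Fold change is
log2((mean_case + c)/(mean_control + c)) with pseudocount
c = 1e-9 x the global intensity maximum (configurable; log-of-means
with a small stabilizer, the common marker-test convention).  BH
adjustment runs across all ions of the comparison; an optional
detection-fraction prefilter (>= 0.1 in either group) exists but is off
by default.  Significance: fold change > 2 or < 0.5 and adjusted
p < 0.01.

## Visualization

Images follow the raster convention (y down, origin at min x/min y);
off-slide cells are NaN.  RGB composites scale each channel by its 99th
percentile (hot-pixel resistant) and clip to [0, 1]; two-ion composites
leave blue at zero.  Colocalization ranks every other ion by Pearson
correlation with the target over pixels and reports the six most
positive and six most negative, the standard panel size.

## Synthetic data generator

The generator plants every structure the pipeline claims to recover,
at a desk scale chosen to keep the full workflow under a minute of
compute: a 60x60 slide, an elliptical tissue (~1900 pixels) split into
3 sub-regions, 120 region-confined structured ions, 80 CSR noise ions,
20 isotope pairs, 10 adduct families (2-3 forms each) and 30
differential ions — about 300 ions total, the same order of magnitude
as a real section's peak list, at ~1/8 the pixel count.

Mechanisms, and the real-data features they emulate:

* *Spatial programs*: each region has a smooth program (Gaussian bump
  of width 10 px on a 0.3 within-region floor).  Ion abundance is
  program x a smooth log-normal field (correlation length 3 px, sigma
  0.4, shared within an isotope/adduct family) x iid log-normal pixel
  noise (sigma 0.3).
* *Detection-limit censoring*: a pixel is detected when its relative
  signal clears a floor (0.1) and survives thinning (p = 0.95), so
  missingness tracks abundance as in real MSI data.
* *Isotopologues*: companions at exactly +1.003355 Da with intensity
  ratio 0.011 x n_C from the generating formula (real metabolite
  formulas are used, so carbon counts and neutral masses are
  chemically consistent) and the parent's detection support.
* *Adduct families*: forms at M + shift sharing one abundance field,
  with form-specific amplitudes ([M+H]+ strongest).
* *Differential ions*: detected tissue-wide, intensity x2 and
  detection rate 0.95-vs-0.35 in their elevated region (abundance and
  missingness move together).
* *Noise ions*: Bernoulli(0.3) everywhere on the slide.
* *Background*: a faint baseline (detection 0.02, scale 200 vs 1e5) so
  total intensity over tissue-enriched ions cleanly separates tissue
  from background; the realized separating threshold is recorded in
  the truth object.
* Unrelated m/z values are rejection-sampled to stay 20 ppm away from
  every isotope/adduct spacing, so planted relationships are the only
  ones present.

One seed drives named substreams (geometry, m/z, each ion class), so
changing one class's count does not perturb another's draws.

What passing these simulations does **not** show: robustness to mass
drift or centroiding artifacts (planted spacings are exact), to
isobaric interference (rejection sampling removes it), to chimeric or
gradient tissue boundaries (regions are crisp), or to
non-stationary background.  Real-data behavior of the thresholds
(score 30, rho 0.5) should be assessed per dataset; the defaults are
starting points, not guarantees.

## Numerical choices and degenerate inputs

* Monoisotopic masses use each element's principal (most abundant)
  isotope — identical to the lightest for CHNOPS and halogens.
* Adduct shifts include the electron mass ([M+H]+ = +1.007276), since
  10 ppm at m/z 100-1000 is sensitive to ~0.5 mDa.
* Zero-variance ions yield NaN Moran's I / Pearson r with a warning
  and are excluded from rankings; a zero-variance *target* is an error.
* Duplicate m/z columns are rejected, not merged (merging is an
  upstream concern); duplicate pixels are always an error.
* Library records keep a user-stated mass even when it disagrees with
  the formula by > 5 ppm (warned), since the stated mass is what the
  user matched against upstream.
* p-values are floored at 1e-300; scores are capped at 300.

## Known limitations

Charge state defaults to 1 everywhere (multi-charge spacing is
supported by parameter but untested against data); MS/MS evidence,
retention time and FDR-style decoy scoring are out of scope; no
reference database content is bundled (the library format is the
interface); pathway analysis is delegated to external tools; and the
web GUI of the original ecosystem is replaced by the CLI and library
surface.
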