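# Methods

`sepalnir` predicts how severely a tomato sepal will be infected by fungus
several days after harvest, from a near-infrared hyperspectral image taken
*before* any infection is visible. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic test bed does and does not show.

## Problem and data model

A line-scan NIR camera images a truss of cocktail tomatoes as a cube
`m(i, j, λ)` — rows × columns × ~224 bands on a 900 nm + k·3.46 nm grid.
White-panel and dark-current reference spectra `w(λ)`, `b(λ)` accompany each
acquisition. Days later, the same sepals are graded 0 (healthy) to 5 (fully
infected) by a panel of graders; the fused grade is the regression target.
The premise is physiological: sepal tissue that is poorly hydrated at
harvest is more vulnerable to fungal colonization, and hydration leaves a
spectral signature — the depth of the water-absorption dip near 1400 nm.

## Pipeline

### Radiometric correction

Reflectance is `(m − b) / (w − b)` per pixel and band. Values are clipped to
[−0.1, 1.5] to bound specular outliers (the bound is configurable; the
clipping is logged in the band report). A band where `w = b` is a hard
error: the correction is undefined there and indicates a broken reference.

### Band selection

Per-band noise σ is the robust Donoho estimate — median absolute deviation
of the finest-level 2-D wavelet detail coefficients divided by 0.6745
(Daubechies-2, via `skimage.restoration.estimate_sigma`). Bands with
σ > 1.5 × min σ are *candidates* for rejection, but only the leading and
trailing candidate runs are discarded, keeping the spectral axis contiguous;
interior candidates (often tissue texture that the MAD estimator reads as
noise) stay. Candidates inside a configurable retain window (default
1580–1660 nm) are kept regardless and flagged `retained_for_segmentation`:
they are noisy but carry spatial contrast the sepal segmentation uses. On
the default synthetic scenes this discards exactly the boosted edge bands
(first 13, last 16, minus the retained tail), keeping ~195–207 of 224
bands. The instrument literature quotes 194 kept bands spanning
980–1660 nm for this camera; those two printed numbers are mutually
inconsistent with the 224-band grid (224 − 13 − 16 = 195), so the package
trusts the σ-threshold rule and reports the count it actually gets.

### Denoising

Two products are built deliberately:

* the **segmentation cube**: per-band 2-D wavelet soft thresholding
  (BayesShrink, db2), then a per-pixel 1-D spectral median filter
  (window 5, reflected edges);
* the **feature cube**: corrected and band-selected only. Sepal tips are
  tens of pixels; spatial smoothing would bleed background reflectance into
  them, so features are extracted from the unsmoothed cube.

### Segmentation

Each pixel's spectrum is SNV-normalized (centered, divided by its
population sd). Pixels whose spectral sd is below a reflectance-scale floor
(default 0.01, the sensor noise level) are treated as spectrally constant
and zeroed: normalizing pure noise to unit variance would manufacture
signal in empty background. The normalized spectrum is filtered with the
first derivative of a Gaussian sampled at integer band offsets,
σ_g = 2.5 band steps, support L = ceil(3σ_g), in the local-difference form

    r(i,j,n) = Σ_{s=−L..L} ( m(i,j,n) − m(i,j,n+s) ) · g′(s)

which is exactly zero for constant spectra. Two significance maps sum |r|
over bands at or below 1150 nm (tomato evidence `t`) and at or above it
(calyx-stem evidence `s`); the split band feeds both sums. The 1150 nm
split is where the across-pixel variance ordering of the two tissue classes
flips. Each map is clipped to its 1st/99th percentiles, min-max normalized,
and thresholded by Otsu's method (256-level histogram).

Class assignment requires both the Otsu claim and raw-map dominance: a
pixel is tomato iff the tomato mask claims it **and** `t ≥ s` there, calyx
iff claimed and `s > t`. Dominance is compared on the *raw* maps: the
percentile rescaling stretches each map to [0, 1] independently, so when
one class is nearly absent its rescaled map inflates tiny values and Otsu —
which always splits — would hallucinate a class. With the raw-dominance
rule a scene with no calyx yields a calyx mask under 0.2% of the frame,
and masks are disjoint by construction. Accuracy is scored with the
Sørensen-Dice coefficient (1.0 when both masks are empty).

### Sepal features

The calyx-stem mask is intersected with the (manually drawn; synthetic
here) sepal identification raster; labels with fewer than 10 surviving
pixels are dropped as slivers. Each sepal is then two vectors over the kept
bands: the per-band mean and the per-band population sd of its pixels.
Identifiers are 4 digits: batch, truss, tomato, sepal.

### Grade fusion

The sepal × grader matrix is column-centered and projected onto the first
principal component of the grader covariance; the sign is fixed so scores
correlate positively with the per-sepal mean grade. Because PC1 scores have
arbitrary scale, they are affinely rescaled by regressing mean grades on
the scores — the fused severity is the fitted value, living on the 0–5
grade scale. This rescaling convention is the package's own (the projection
alone cannot produce grade-scale numbers); it makes fusion equivariant
under adding a constant to all grades. A zero-variance panel degenerates to
the common grade with explained-variance ratio 1.

### Severity models

Features are the concatenated mean and sd spectra (2 × kept bands). Two
regressors are supported: Random Forest and gradient-boosted trees
(XGBoost), both single-threaded and seeded. Hyperparameters are tuned by
exhaustive grid search maximizing mean CV R²; the default grids are small
and standard (RF: 200/500 trees × depth ∞/10 × features sqrt/0.33; XGB:
200/500 trees × depth 3/6 × learning rate 0.05/0.1) and fully overridable.
Two CV schemes: shuffled 10-fold, and group k-fold with batches as groups
(one fold per batch; no batch ever straddles train and validation). The
winner is refit on the whole 80% training split and scored on the 20%
hold-out with RMSE, R² and Pearson r; the experiment repeats over seeded
random splits (default 5) and reports mean and sd of each metric. R² with
constant predictions leaves Pearson undefined; it is reported as 0 with a
flag. Sepal predictions and truths are averaged per tomato (first three id
digits) for the fruit-level correlation.

### Interpretation

Global: impurity-based feature importances normalized to sum 1, reported
against wavelength and family (mean vs sd). Local: exact path-dependent
TreeSHAP. For sklearn forests the package implements the polynomial
algorithm directly (`sepalnir._treeshap`) — validated in the test suite
against brute-force Shapley enumeration over feature coalitions on small
trees — and for XGBoost it uses the library's native `pred_contribs`.
Additivity (baseline + row sum = prediction) holds to ~1e−14 for the own
implementation; XGBoost computes contributions in float32, so ~1e−5 there.
Per-instance reports list features by |contribution| with sign (positive
pushes the predicted severity up).

`restrict_wavelengths` rebuilds the design matrix from the bands in a
window (default 1390–1420 nm, ~9 bands per family on the instrument grid)
so a reduced-range model can be compared against the full-range one.

## Synthetic scenes

The generator emulates the features of real acquisitions the pipeline
depends on, and nothing else:

* geometry: trusses laid out on a grid, one tomato disk per cell with a
  fan of labeled sepal wedges above it; masks are exact by construction;
* spectra: smooth parametric curves — logistic ramps plus Gaussian dips —
  not radiative transfer. Tomato pixels carry a steep ramp and per-pixel
  variability below 1150 nm; sepal pixels carry a 1400 nm dip whose depth
  rises with a latent hydration h ∈ [0, 1] and a severity-independent
  1200 nm dip (planted so interpretation checks can confirm the model
  ignores that second water band); background is flat and dark;
* latent severity is 5(1 − h), strictly decreasing in hydration, so mean
  reflectance near 1400 nm is positively informative by construction;
* sensor: raw = black + reflectance × (white − black) + Gaussian noise
  (sd 1% of dynamic range), boosted ×3 on the first 13 and last 16 bands —
  flat-field correction inverts the construction exactly at zero noise;
* panel: grade = clip(severity + grader bias (sd 0.1) + noise (sd 0.25),
  0, 5) for 11 graders, giving PC1 explained variance ≳ 0.95.

Default study: 6 batches × 2 trusses × 3 tomatoes × 5 sepals = 180 sepals
on 112×168 px scenes — a deliberate desk-scale reduction of a full
experiment (~110 sepals per batch); the structure, not the size, is what
the tests exercise.  The reproduction script (`scripts/acceptance.py`) runs
this default study with two repeated train/test splits per model/CV
combination, and the interpretation analyses reuse the grid-search winner
rather than re-tuning — sizes chosen so the whole recomputation fits
comfortably on a single core. Multi-batch studies reuse the band selection estimated
on the first scene so feature vectors align across batches.

**What passing tests do not show:** synthetic spectra are far cleaner than
biological tissue, the hydration→severity link is noiseless by
construction, and batches differ only by seed, not by grower or cultivar.
Recovery metrics here (Dice ≈ 0.99, R² ≈ 0.99) are upper bounds
demonstrating correctness of the machinery, not expected field performance;
on real data this class of pipeline reports R² around 0.5–0.7 and
fruit-level correlations near 0.9.

## Numerical choices

* SNV and sepal sd use the population convention (divide by n).
* Spectral edges: reflection padding for the derivative filter and the
  median filter (scipy's edge-inclusive `reflect`).
* Otsu runs on a 256-bin histogram; binned thresholds are not exactly
  invariant under monotone intensity transforms (a boundary pixel may
  flip), which the tests acknowledge.
* DoG kernel taps are sampled at integer band offsets (index domain, not
  nm), matching a convolution over band index.
* Ties in mask dominance go to tomato (`t ≥ s`).
* Batch letters map A→1 … F→6 in the 4-digit sepal id.
* All RNG flows through `numpy.random.default_rng` seeds; estimators run
  single-threaded with fixed `random_state`, so identical configs
  reproduce every artifact byte-for-byte through the CLI.

## Known limitations

* The ENVI reader supports the common BIL/BIP/BSQ uncompressed dialects
  with a wavelength list; exotic header features (bad-band lists, gain
  arrays, BIL with header offset) are out of scope.
* Sepal instance identification is taken as given (a labeled raster); the
  package does not attempt automatic instance segmentation.
* Group k-fold uses one fold per batch; with very few batches the CV
  estimates are coarse.
* The own-TreeSHAP path is pure Python: exact but slow for very deep
  forests on many samples; explanation sets are subsampled by default
  (`shap_samples`) in long experiments.
* Severity is modeled per sepal independently; spatial correlation between
  sepals of one tomato is ignored except through the final averaging.
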