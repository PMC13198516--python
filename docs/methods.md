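# Methods

`carospec` implements an automated analysis chain for single-cell Raman /
SERS data of carotenoid-producing plant cell cultures: spectral
preprocessing, selection of characteristic carotenoid bands from pure
standards, triage of Raman-map pixels into informative and non-informative
spectra, construction of representative spectra per cell line, and
regression of the per-line carotenoid composition (astaxanthin,
canthaxanthin, β-carotene) with a multi-layer perceptron. A synthetic
spectral simulator with exact ground truth stands in for instrument data
and defines the benchmark all tests run against.

## Spectral model and simulator

A simulated spectrum on a wavenumber grid ν (default 850–1750 cm⁻¹ at
1 cm⁻¹ spacing) is

I(ν) = A · Σ_c f_c · Σ_p L(ν; center_p, fwhm_p, amp_p) + B(ν) + ε(ν) + spikes

* **Bands** are Lorentzian, the standard line shape for Raman bands, with
  FWHM 12 cm⁻¹ for the fingerprint modes. The three compounds carry their
  υ₃ / υ₂ / υ₁ modes at the published positions (astaxanthin 1009 / 1160 /
  1516 cm⁻¹; canthaxanthin 1011 / 1161 / 1518; β-carotene 1011 / 1160 /
  1518), υ₂ normalized to 1 as the reference band and υ₁ slightly weaker
  (0.88–0.95), υ₃ weak (0.30–0.45). Each compound additionally has one weak
  (≈0.1) compound-specific minor band so that mixtures of the three nearly
  identical fingerprints remain spectroscopically identifiable — without
  such fine structure the 3-component regression problem would be
  ill-posed, which real carotenoid spectra (differing in fine structure,
  band areas and small shifts) are not.
* **Mixtures are linear**: the noise-free signal is exactly
  Σ_c f_c · fingerprint_c, with amplitude scale A = 1000 counts for a pure
  compound (signal-to-noise ≈ 100 at the default noise, consistent with
  resonance-enhanced carotenoid signals at 532 nm excitation).
* **Background** B(ν) is a cubic polynomial (coefficients (400, −150, 60,
  −30) counts over the normalized grid coordinate) plus one broad Gaussian
  (amplitude 300, center 1250 cm⁻¹, σ 300 cm⁻¹) emulating residual
  fluorescence.
* **Noise** is i.i.d. Gaussian, σ = 10 counts.
* **Cosmic-ray spikes** are 1–2 grid points wide, 5–20× the spectrum
  maximum, Poisson-distributed with mean 0.2 per spectrum — the artifact
  class modified-z-score despiking targets.

Cell maps place carotenoids in randomly positioned discs ("vesicles",
matching the vesicle-like storage structures seen in engineered cell
lines); pixels inside a disc carry the line's mixture fingerprint with a
per-pixel amplitude jitter uniform in [0.6, 1.4], all other pixels carry
only background and noise. Lines with total carotenoid content < 0.15 are
simulated "wild-type-like" (2 vesicles of radius 1.5 px, < 5 % informative
pixels); richer lines get 4 vesicles of radius 2.5 px. The default
benchmark is 7 cell lines × 4 maps of 20×20 pixels plus a standards set of
34 spectra (12 + 11 + 11), the size of a quality-filtered standards
dataset. The 7-line label table shipped as `default_label_table()` is a
synthetic stand-in for an HPLC quantification table: wild-type lines carry
trace β-carotene only, engineered lines mix all three compounds.

Every stochastic operation is a pure function of its inputs and a seed
(NumPy `SeedSequence` spawning), so benchmarks are bit-reproducible.

**What the simulator does not emulate:** SERS enhancement physics and
surface-selection effects, wavenumber calibration drift, detector etaloning,
pixel-to-pixel focus variation, chlorophyll autofluorescence, and real
within-class spectral variability beyond additive noise and amplitude
jitter. Passing tests therefore demonstrate correctness of the analysis
chain under a controlled, linear, well-calibrated spectral model — not
performance on any particular instrument's data.

## Preprocessing

* **Baseline**: arPLS (asymmetrically reweighted penalized least squares).
  The baseline z minimizes ‖W^{1/2}(y−z)‖² + λ‖Dz‖² with D the second
  difference; weights are updated from the logistic
  w_i = 1/(1+exp(2(d_i − (2σ_d − μ_d))/σ_d)) of the residuals d = y − z,
  where μ_d, σ_d are mean and SD of the negative residuals, and iteration
  stops when the weight vector changes by < `arpls_ratio` (relative L2) or
  after `arpls_max_iter` iterations (last iterate returned with a logged
  warning — on realistic spectra the weights keep oscillating at ~1e-3
  without the baseline moving, so a hard failure would be wrong). Defaults
  λ = 1e5, ratio = 1e-6, max_iter = 50 (the reference regime of the
  method); the pentadiagonal system is solved in banded form. arPLS is
  equivariant under adding a constant and reproduces a peak-free smooth
  input exactly.
* **Despiking**: modified z-score of the first differences,
  z = 0.6745(ΔI − median ΔI)/MAD(ΔI), threshold 6 (the method's reference
  value). Plain thresholding flags both endpoints of every large jump, so
  it marks the clean neighbour of a 1-point spike, misses the interior of a
  2-point spike, and fires on the steep flanks of genuine Raman bands
  (whose difference z-scores are also large, especially at low noise). Two
  refinements fix this: candidate *runs* longer than 4×`spike_window`
  points are treated as spectral features, never spikes (a cosmic ray spans
  at most ~2 points plus its edges); and a remaining candidate is confirmed
  only if it deviates from the straight line joining its nearest
  non-candidate neighbours by more than threshold × MAD/0.6745. Confirmed
  spikes are replaced by the mean of non-spike neighbours within
  ±`spike_window` (default 3), widening the window if necessary. A constant
  spectrum (MAD = 0) is returned unchanged. Despiking is idempotent.
* **Quality filtering**: per class, spectra whose Pearson correlation with
  the class mean is below 0.9 are discarded in a single pass. ("Deviates
  significantly from the average" is operationalized as a correlation
  cutoff because it is scale-free; the threshold is config-exposed.) A
  class losing all spectra is an error.
* **Interpolation**: linear, onto the common feature grid of 412 points
  spanning 900–1700 cm⁻¹ (the fingerprint window); extrapolation is
  refused. 412 is the feature count of the regression network.
* **Scaling**: per-feature min–max to [0, 1], fitted on training folds only
  (the fitted object carries nothing but training statistics, so test
  information cannot leak); constant features map to 0.

## Characteristic peaks

Peaks are local maxima with topographic prominence ≥ 5 % of the spectrum
range (`scipy.signal.find_peaks`). The k-most-important procedure detects
peaks in each compound's mean spectrum, normalizes prominences per
compound (making the ranking invariant to rescaling any one compound),
clusters centers across compounds within a 5 cm⁻¹ tolerance
(greedy single-link on the running cluster mean), and ranks clusters
lexicographically by (number of compounds sharing the band, mean
normalized prominence). With k = 2 the procedure selects the υ₂
(~1160 cm⁻¹) and υ₁ (~1517 cm⁻¹) bands — the two bands common to all three
carotenoids. Band intensities are read as the window maximum within
±5 cm⁻¹ rather than a point lookup, tolerating the few-cm⁻¹ band shifts
that occur between carotenoid species.

Class separation is quantified on unit-L2-normalized spectra: intra-class
distance = mean pairwise Euclidean distance within a class; inter-class
distance = distance between class means; separation ratio = mean inter /
intra per class (undefined and flagged when intra = 0).

## Knee-point triage

Each map pixel gets the score f = Σ over the characteristic peaks of the
window-max intensity, computed before baseline correction. The scores of a
map are sorted ascending and the knee of the curve is the index maximizing
the perpendicular distance to the chord joining the endpoints after
normalizing both axes to [0, 1] (Kneedle-style with sensitivity 1; ties
break toward the larger index; a curve whose maximum distance is below
1e-9 — all-equal scores or an exact ramp — is degenerate and yields zero
informative spectra). Spectra strictly after the knee are informative.

One deviation from the strict stage order: cosmic rays are removed from
the *scored copy* of each spectrum before scoring (`despike_before_scoring`,
default on, config-exposed). A single spike inside a scoring window
stretches the [0, 1] normalization so far that the knee collapses onto the
outlier and the informative group shrinks to a handful of pixels; despiking
only the copy used for scoring restores robustness while the spectra handed
to later stages remain raw (baseline correction and despiking are still
applied only to the informative group).

## Representative spectra and dataset assembly

Per cell line, the informative spectra of all its maps are pooled (count
N), preprocessed, and summarized by repeated random-half averaging: 10
times, ⌈N/2⌉ distinct spectra are drawn uniformly without replacement and
averaged. Subsamples are drawn independently across repeats (overlap
allowed — the simplest faithful reading of repeated random halving), and
odd N rounds up. Seven lines × 10 repeats give 70 representative spectra;
with the 34 standards (one-hot composition targets, since a pure compound
is 100 % of itself) they form the 104 × 412 training matrix. Each
representative's target is its line's label-table composition.

## Regression model and evaluation

The regressor is a feed-forward MLP 412–100–10–3 with tanh hidden
activations (scikit-learn `MLPRegressor`), trained by L-BFGS (default,
max_iter 1000) or ADAM (max_iter 2000). The L2 penalty `alpha` defaults to
0.1: the network has ~42 000 weights against ~83 training spectra, and in
design-phase experiments the unregularized fit memorized training folds
(train R² 0.9999) while held-out R² dropped by ~0.03; 0.1 was fixed as the
decade giving stable held-out accuracy across benchmark realizations.

Cross-validation uses multi-label stratification: each of the three
continuous outputs is discretized into 4 quantile bins, every
(output, bin) pair becomes a binary label, and samples are distributed by
the iterative-stratification greedy scheme (rarest label first, assign to
the fold with greatest remaining demand; ties by remaining capacity, then
a seeded random choice). Fold sizes are forced to differ by at most one.

Metrics are MSE, MAE and R² = 1 − SS_res/SS_tot, computed per output and
uniformly averaged over the three outputs (variance weighting is the
config-exposed alternative); R² of a zero-variance output is undefined and
excluded from the average with a warning; negative R² values are carried
unclipped. The evaluation harness repeats the whole cycle n_runs times
(default 50), each run drawing a fresh stratified split and training once
per fold; a run's test metrics are computed on the pooled held-out
predictions (every sample held out exactly once per run) and the report
aggregates mean, SD and best per measure. Per-run iteration counts are the
mean over folds.

## Map rendering

Carotenoid distribution images take, per pixel, the window maximum (or
trapezoidal integral) of the baseline-corrected spectrum over the
1500–1560 cm⁻¹ ν(C=C) window. Window-max is the default because it is
robust to the small band shifts between carotenoid species. Rendering is
equivariant with map transposition. Export writes a PNG with a colorbar
spanning the data range plus a CSV of the raw values so external tools can
overlay bright-field images.

## Problem sizes and numerical choices

The shipped benchmark (7 lines × 4 maps × 400 pixels, 34 standards,
50-run × 5-fold evaluation) was sized so a full analysis runs in minutes
on a single core while leaving every stage's statistics meaningful; map
dimensions, run counts and all thresholds above are config-exposed.
Tie-breaks are deterministic throughout (knee: larger index; peak ranking:
lower wavenumber; stratification: seeded). Degenerate inputs are handled
explicitly: constant spectra (despike, knee), zero-variance features
(scaler) and outputs (R²), empty representative pools (error naming the
line).

## Known limitations

* The triage rule assumes a map contains a meaningful split; on maps with
  barely any carotenoid signal (the wild-type-like lines) the knee falls
  inside the noise tail and the "informative" group is essentially the
  brightest noise pixels. The downstream regression is robust to this —
  those lines' labels are near zero — but per-pixel masks for such maps
  should not be over-interpreted.
* HPLC-style labels are population-level averages; the model learns
  population-informed spectral patterns, not single-cell concentrations.
* The peak-importance ranking assumes the informative bands are shared
  across compounds; a compound identified only by a private band would
  need a larger k.
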