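# Methods

## The measurement and the problem

Wideband absorbance immittance (WAI) records the fraction of incident
acoustic energy the middle ear absorbs, as a joint function of probe
frequency and ear-canal pressure. One measurement is therefore a surface
`A(f, P) ∈ [0, 1]` which this package discretises on a canonical grid of
107 geometrically spaced frequencies (226–8000 Hz) by 51 pressures
(−300…+200 daPa in 10-daPa steps) — 5457 points per ear. Otitis media
with effusion (OME) lowers absorbance, most strongly below ~2 kHz, so the
surface carries diagnostic signal; the package's job is to (i) map where
normal and OME ears differ, (ii) extract compact discriminative regions,
and (iii) benchmark classifiers that read the whole surface.

The clinical cohort this pipeline was designed around (672 ears: 423
normal, 249 OME) is not publicly deposited. All empirical claims the
package itself makes are therefore properties demonstrated on its
synthetic cohort generator, which reproduces the printed surface
statistics of that cohort.

## Synthetic cohort generator

Each class is a deterministic template plus heteroscedastic Gaussian
noise, clipped to `[0, 1]`:

* **Template**: baseline plus a sum of separable Gaussian bumps in
  (log2 frequency, pressure). The default normal-ear template attains
  0.39 at (820 Hz, 0 daPa), 0.50 at (1335 Hz, +20 daPa) and its global
  maximum 0.76 at (3270 Hz, +65 daPa); the OME template a single peak of
  0.50 at (5000 Hz, −30 daPa). Bump *amplitudes* are solved from a small
  linear system at config-load time so the summed template attains each
  target value exactly at its centre despite overlapping tails. Bump
  *widths* are not anchored by any printed number; they were chosen once
  so that each class mean has a well-defined single maximum at grid
  resolution (the clinical contours are broad plateaus whose exact shape
  is not recoverable from printed values), and are recorded in
  `src/waiome/configs/default_generator.yaml`.
* **Noise**: independent per grid point, variance given by a baseline
  plus Gaussian hotspots — 0.07 for normal ears (1834–2370 Hz at
  −300…−110 daPa, and ~5.3 kHz near 0 daPa), 0.11 for OME ears
  (3.7–5.5 kHz at +40…+200 daPa). Independence is the minimal assumption
  given that only means and variances are reported. A configuration hook
  (`noise_blur_sigma`, off by default) Gaussian-blurs the noise field and
  rescales it to unit pointwise variance, producing spatially correlated
  noise for experiments that need genuinely overlapping classes.
* **Clipping**: samples are clipped to the physical `[0, 1]` range. This
  matters: where the template is within ~1σ of a bound the realised mean
  and variance of a sample differ from the raw template (e.g. at the
  normal-class variance hotspot, template ≈ 0.11 with σ ≈ 0.26, the
  realised mean is ≈ +0.06 above the template and the realised variance
  ≈ half the configured value). `expected_mean_surface` and
  `expected_variance_surface` give the exact clipped-Gaussian moments in
  closed form; all convergence tests compare samples against these, not
  against the raw template.
* **Pressure axis realism**: each ear's raw axis is the canonical one
  thinned by dropout (default 0.15) and jittered (default σ = 3 daPa),
  emulating uneven device sampling; a floor of 4 retained samples mirrors
  the completeness rule below.
* **Cohort structure**: ears are assigned to participants at the
  emulated ears-per-participant ratios (423/242 normal, 249/163 OME), so
  grouped cross-validation can be exercised. Bilateral-ear correlation in
  the absorbance values themselves is *not* modelled — surfaces from the
  same participant are independent draws — so passing tests say nothing
  about within-participant dependence in real data. Ages are uniform on
  the reported ranges and carry no effect on the surfaces.

What passing tests on this generator do show: the statistical map, region
extraction and classification machinery behave correctly on data with the
reported first- and second-moment structure. What they do not show:
performance on real ears, whose within-class structure (multimodality,
age effects, bilateral correlation, artefact patterns) the generator does
not emulate. Real-data benchmark figures are therefore never asserted.

## Pre-processing

Raw sweeps are moved onto the canonical pressure grid one frequency row
at a time with PCHIP (monotone piecewise cubic Hermite) interpolation,
which preserves monotonicity and cannot overshoot — important for data
bounded in `[0, 1]`. Outside the measured pressure range the boundary
value is held constant rather than extrapolated (cubic extrapolation is
unbounded; clamping is the conservative choice). Records with fewer than
4 distinct pressure samples are rejected as incomplete sweeps — the
package's operationalisation of a qualitative "poor quality" exclusion;
likewise absorbance outside `[0, 1]` by more than 1e-6 rejects a record
at file-reading time.

Surfaces are flattened frequency-major (`index = f_idx·51 + p_idx`) to
5457-vectors, fixed so forest importances map back to grid coordinates
deterministically. Standardization (zero mean, unit variance per feature)
is fit on training folds only and applied to test folds; features with
sd < 1e-12 are centred but not scaled. A global-scaling mode exists for
comparison but per-fold is the default, being the leakage-free choice.

## Pointwise rank-sum maps

At each grid point a two-sided Wilcoxon rank-sum test compares the two
groups: mid-ranks for ties, tie-corrected variance, continuity
correction, normal tail; for total N ≤ 12 the exact permutation
distribution of the rank sum is enumerated instead (two-sided p =
`min(1, 2·min(P(W≤w), P(W≥w)))`). No multiplicity adjustment is applied
by default — the map is a descriptive field, and the headline
"fraction of significant points" statistic is defined on raw p-values —
but a Benjamini–Hochberg option exists for sensitivity analysis.

Top-k% regions select the `k = round(fraction·5457)` smallest p-values
(half-away-from-zero rounding, so 10% → 546 and 5% → 273 points), with a
deterministic tie-break: smaller p, then larger |z|, then frequency
index, then pressure index.

## Forest importance maps

Ten random forests with 10, 20, 30, 40, 50, 100, 200, 300, 400 and 500
trees are each fit on the full vectorized cohort; their normalized
mean-impurity-decrease importances are averaged and reshaped onto the
grid (an averaged map that again sums to 1). Fitting on the full data —
not within CV folds — is deliberate: this stage is feature selection,
not performance estimation. Splits consider √5457 ≈ 74 features;
importances are the forest default (impurity decrease), with permutation
importance available behind a flag. Forests are unweighted here.

## Classifier zoo and evaluation

Fourteen fixed designs: KNN (K = 1, 3, 15; uniform weights, Euclidean),
SVM (linear, degree-3 polynomial, RBF, sigmoid kernels), random forest
(10, 100, 500 trees), two feedforward networks and two convolutional
networks. The networks are implemented in a minimal numpy module
(`waiome.nn`) with exactly the layers the designs need; their parameter
totals (trainable weights plus batch-norm statistics) are pinned in
tests: FNN1 5,558,201; FNN2 6,008,701; CNN1 1,754,921; CNN2 5,338,621.
Reproducing these totals fixes two design ambiguities: convolutions use
'same' spatial padding, and CNN2 carries batch normalization after every
convolutional layer (CNN1 has none after its dense layer).

Evaluation is stratified k-fold cross-validation at ear level (default
10 folds), scaler fit per training fold, with 3 random restarts for the
randomized families (rf, fnn, cnn) and 1 for knn/svm; metrics (accuracy,
AUROC from continuous scores, per-class precision/recall/F1) are
averaged over folds then restarts. A `group_by_participant` option keeps
both ears of one participant in the same fold, since bilateral ears
would otherwise straddle folds. SVM scores are signed decision margins
(thresholded at 0); KNN scores are neighbour vote fractions.

Training hyperparameters for the networks are not externally specified;
the defaults are Adam at 1e-3, batch 32, up to 100 epochs with early
stopping (patience 10 on a 10% validation slice of the training fold),
binary cross-entropy. Harness tests and the analysis drivers use short
schedules (3–8 epochs, batch 16, learning rate 3e-3) — chosen as the
package's desk-scale problem sizes — and state them explicitly.

Class imbalance is handled by cost-sensitive learning: OME
misclassification errors are weighted `ome_weight`× in the training loss
(per-sample weights in the networks' weighted cross-entropy,
`class_weight` for svm/rf; KNN has no training loss to weight). For the
emulated 423/249 cohort the recommended weight is 423/249 ≈ 1.7. The
imbalance experiment uses a cohort with spatially correlated noise
(blur σ = 12 grid cells) because with independent pointwise noise the
5457-dimensional classes are essentially separable and every recall
saturates at 1; correlated noise reduces the effective evidence per ear
and produces the regime where weighting visibly moves minority recall.

## Numerical choices and degenerate inputs

* Rank-sum variance ≤ 0 (all values tied) → z = 0, p = 1.
* Exact-mode comparisons use a 1e-9 slack when counting `W ≤ w_obs` to
  absorb floating-point error in mid-rank sums.
* The scaler refuses < 2 training vectors; CV refuses folds that would
  contain a single class, naming the remedy (fewer folds).
* Generator configs validate widths > 0, non-negative variance fields,
  dropout ∈ [0, 1); a dropout draw leaving < 4 pressure samples is
  topped back up to 4 (vanishingly rare at the default rate).
* The frequency grid is geometric with endpoints pinned exactly at 226
  and 8000 Hz; 1/24-octave spacing over that range would give ~124 bins,
  inconsistent with the 107-bin count all downstream arithmetic uses, so
  the 107-bin geometric grid is canonical here.
* All stochastic stages take explicit seeds; identical (config, seed)
  reproduce cohorts, maps, fits and pipeline summaries bit-for-bit
  (summaries contain no timestamps).

## Problem sizes used by the test suite and acceptance script

Calibration checks average 400 surfaces per class; the type-I-error
harness uses 50+50 null ears across all 5457 points; planted-region
recovery uses 100–150 ears per class; the imbalance experiment uses a
102/60 cohort with 3-fold CV and 8-epoch CNN2 training; harness sanity
checks use a 30/18 separated cohort. These sizes are the package's
desk-scale choices and are stated in the tests that use them.

## Known limitations

* The generator is first-and-second-moment faithful only; no age
  structure, no bilateral correlation, no artefact model.
* Peak *widths* in the templates are package choices; figures derived
  from the synthetic cohort should not be read as clinical contours.
* The numpy networks are CPU-only and deliberately minimal; they exist
  to realise the four fixed designs, not as a general training library.
* Real-data benchmark metrics are out of reach without the clinical
  dataset; the classifier tables produced here characterise the harness
  on synthetic data only.
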