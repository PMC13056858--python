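# Methods

`peptidiag` implements a complete serum MALDI-TOF peptidome diagnostic
workflow — preprocessing, peak detection and alignment, an eight-classifier
bench, attribution-based core-biomarker selection, and clinical-utility
evaluation — together with a ground-truth synthetic cohort generator that
makes every stage testable end to end.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic cohort generator

The generator emulates a two-class serum peptidome case/control study.
Each sample's profile spectrum on a uniform m/z grid (default 0.5 Da over
1,000–10,000 Da; 18,001 points) is

```
I(m) = s · ( Σ_k a_k · N(m; μ_k(1 + δ·1e−6), σ_k) + B(m) ) + ε(m),  clipped at 0
```

- **Peak panel.** 150 Gaussian peptide peaks, evenly spaced (~59 Da apart,
  several alignment tolerances even at the top of the range) with a small
  fixed jitter.  Peak width is σ = 300 ppm × m/z, floored at 1.5 Da so that
  every peak spans several grid points at the default pitch — an
  undersampled peak is not a resolvable one.  Base areas are log-uniform
  over 30–300 (arbitrary units), spanning the detection dynamic range;
  fifteen null peaks have prevalence 0.8 so missing-value handling is
  exercised.
- **Planted effects.** Twelve peaks spread over the mass range carry log2
  fold changes of ±1.0–1.6 (cancer vs. control).  Their lower-abundance
  class keeps a mean area of 120, comfortably above the detection limit:
  planted-effect recovery should measure the selection method, not detector
  luck at the SNR edge.
- **Biological variation** is log-normal per peak per sample with CV 0.20
  (areas are strictly positive).  **TIC variation** is a log-normal
  per-sample global scale with CV 0.15.  **Mass-axis drift** is a
  per-sample relative shift, Gaussian with SD 150 ppm — well inside the
  2,500 ppm alignment tolerance, as instrument drift is in practice.
- **Baseline** defaults to A·exp(−(m − m_low)/τ) with A = 50, τ = 1,500 Da,
  mimicking matrix chemical background; a polynomial shape is available.
- **Noise** is additive Gaussian (SD 0.5 intensity units) clipped at zero —
  the simplest model that exercises SNR-based detection.
- **Matrix-cluster artifacts**: five extra class-neutral peaks at fixed
  positions inside 1,500–2,000 Da (area CV 0.5), placed midway between
  panel peaks, standing in for MALDI matrix chemistry.

What the generator does **not** model: isotope envelopes, adducts, detector
saturation, replicate spots, peak-shape asymmetry, heteroscedastic noise,
or batch effects.  Passing tests therefore demonstrate correctness of the
pipeline's algorithms under controlled conditions, not performance on real
sera.

## Preprocessing

Order: TIC normalization → Savitzky–Golay smoothing → adaptive iterative
baseline correction, with an optional (default on) re-normalization after
baseline subtraction so that relative peak areas stay comparable across
samples.

- **TIC normalization** scales each spectrum to a common total ion current
  (default 1e6; the value is arbitrary and cancels in all ratio-based
  statistics).
- **Smoothing**: Savitzky–Golay, default window 11 points (5.5 Da),
  polynomial order 3.  The window must stay narrower than the narrowest
  peaks (6σ = 9 Da at the width floor); a wider kernel measurably
  annihilates low-mass peaks.
- **Baseline**: iteratively reweighted asymmetric penalized least squares
  (airPLS-style).  The baseline z minimizes Σ w_i(y_i − z_i)² +
  λ Σ(Δ²z)², λ = 1e7 by default; points above z get weight 0, points below
  get weight exp(t·|d_i|/‖d−‖₁) at iteration t, and the two boundary points
  are anchored.  Convergence when the negative-residual mass falls below
  1e−3 of total intensity, max 15 iterations.  Negative corrected
  intensities are clipped to zero.  On the default synthetic spectra the
  injected exponential background is recovered with RMSE ≈ 1% of its
  amplitude in peak-free regions.

## Peak detection and alignment

- **Noise estimation**: per-point noise is the sliding-window (200 Da)
  quantile spread q(0.8413) − q(0.5), which equals 1 SD for Gaussian noise
  — the same population quantity as 1.4826 × MAD — but remains unbiased
  after the zero-clipping introduced by baseline subtraction, since
  clipping only displaces quantiles below the median.  Rolling quantiles
  are evaluated at quarter-window anchors and interpolated.
- **Detection**: local maxima whose height *above the rolling-median local
  floor* exceeds snr_min (default 3) × local noise.  Measuring height,
  centroid (height-weighted mean over the half-height support) and area
  (trapezoid of floor-relative height over that support) relative to the
  local floor makes the features insensitive to any residual background
  the baseline corrector leaves behind.  A threshold of 3σ on a smoothed
  (hence correlated) noise floor necessarily passes a small tail of the
  ~2,000 noise maxima per spectrum; these false peaks do not align across
  samples and are removed by the bin support filter.
- **Matrix-cluster exclusion** removes peaks that are *both* inside
  1,500–2,000 Da *and* within tolerance of a listed artifact m/z — genuine
  peptide peaks in that region survive.  The simulator's injected artifact
  list is the default; real-data users supply their own.
- **Alignment**: iterative greedy binning at 2,500 ppm.  Seeds are taken in
  descending support-weighted intensity (peak area × number of pooled peaks
  within tolerance, precomputed once by binary search; ties broken by lower
  m/z).  Each bin collects per sample the nearest unassigned peak within
  tolerance of the running intensity-weighted consensus and re-evaluates
  membership until stable (max 10 passes); members outside tolerance of
  the final consensus are dropped, making the tolerance a hard guarantee.
  On clustered instances of ≤ 12 peaks the greedy partition equals the
  exhaustive minimal-bin partition (brute-force cross-check in the test
  suite).
- **Feature matrix**: samples × bins of relative areas.  Missing cells are
  zero-filled by default or interpolated as the mean of the sample's
  nearest flanking bins (zero at the edges); bins supported by fewer than
  10% of samples are dropped, which yields ~150 bins under the default
  cohort.  All imputation is recorded in a mask.
- **Differential screen**: per bin, log2FC = log2((mean_TC + ε)/(mean_HC +
  ε)) with a scale-invariant pseudocount ε = 1e−6 × grand mean; p-values
  from Welch's t on log areas (Mann–Whitney available), BH-adjusted.
  Top-k selectors by |log2FC| and by p are provided.

## Classifier bench

A stratified per-class 80/20 split (banker's rounding of test counts; for
414/430 this gives a test set of 83 + 86).  Eight families: SVM (RBF,
probability-calibrated), k-NN, XGBoost, AdaBoost, LightGBM, Gaussian naive
Bayes, decision tree, random forest — each at its library's conventional
defaults with a fixed seed; SVM and k-NN get a train-fitted z-score step,
tree families consume raw areas.  Held-out metrics: AUC, accuracy,
precision, recall, F1, average precision, with confusion matrices at
threshold 0.5 and stratified 5-fold CV AUC (mean ± SD) on the training
partition only.  PCA / kernel-PCA / t-SNE projections are available for
visual QC.

## Attribution and core-feature selection

Three importance methods, each aggregated across model families by mean
rank:

- **Gini**: normalized impurity-decrease importances of random forest and
  XGBoost.
- **Shapley**: exact additive attributions from the tree libraries' own
  path-dependent algorithms (LightGBM/XGBoost `pred_contrib`, additive to
  the raw margin within float32 precision), or a seeded permutation-
  sampling estimator for any probability classifier.  The sampler switches
  features from a background row to the target along random permutations;
  because each permutation telescopes to f(x) − f(b), local accuracy
  (Σφ + E[f] = f(x)) holds to machine precision by construction.
- **Local surrogates (LIME-style)**: per evaluated instance, 1,000 Gaussian
  perturbations scaled by the training SDs, weighted by an exponential
  locality kernel (width 0.75·√p), fitted with ridge regression to the
  model's positive-class **log-odds**.  A well-fitted diagnostic model's
  probabilities saturate at 0/1 where they carry no local gradient; the
  log-odds do not.

The **core feature set** is the intersection of the Shapley and LIME top-20
lists.  Default families for both methods are LightGBM and random forest:
exhaustive greedy boosting (XGBoost defaults) concentrates credit on one
or two members of a collinear biomarker panel — a faithful description of
that model, but useless for recovering the full panel — whereas LightGBM
and random forest distribute credit across correlated features.  All
family choices are configuration options.

## Evaluation

- **Simplified-model rebuild**: the whole bench retrained on the shared
  core features with the *same* split; restriction to all features is
  verified to be the identity.
- **Single-marker ROC**: orientation-corrected empirical AUC, equal to the
  normalized Mann–Whitney U (cross-checked).
- **Decision-curve analysis**: NB(pt) = TP/N − (FP/N)·pt/(1 − pt) on the
  grid 0.01–0.99 step 0.01 (pt = 1 is excluded as degenerate; ties count
  as positive), against treat-all and treat-none.  The summary area is the
  raw trapezoidal integral of NB over the grid, negative stretches
  included; prevalence is taken from the evaluated set.  For a perfect
  classifier the area is prevalence × 0.98 (≈ 0.48 at the default cohort's
  49% test prevalence).
- **Unsupervised check**: bisecting k-means and Birch (k = 2) on log1p
  areas of the core features, scored by adjusted Rand index against the
  diagnosis, with optional 2-D UMAP embeddings.

## Orchestration and reproducibility

`run_pipeline` executes simulate → preprocess/peaks → bench → explain →
evaluate, persisting every tabular artifact (sample sheet, ground truth,
feature matrix, labels, differential table, metrics, importances, core
set, DCA curves, manifest) under one output directory.  One global seed is
fanned out to per-stage seeds through `numpy.random.SeedSequence`;
re-running a config reproduces all deterministic artifacts bit-identically
(manifest equality is tested).  Raw spectra are persisted only on request
(`save_spectra="csv"|"mzml"`) — at study scale they are ~300 MB of text.
mzML is written and read by a minimal in-package implementation
(uncompressed little-endian float64, bit-exact round trip; the reader also
accepts 32-bit and zlib-compressed arrays).

## Problem sizes used in validation

The validation suite runs the full pipeline at the emulated study scale
(414 + 430 samples, 18,001-point spectra) across 10 seeds for planted-
signal recovery, a 100 + 100 null cohort across 20 seeds for the
false-positive control, and 100 clustered instances of ≤ 12 peaks for the
alignment oracle.  The acceptance script uses one study-scale run plus 5
null seeds.

## Known limitations

- The synthetic spectra are far cleaner than real serum MALDI profiles;
  held-out AUCs near 1.0 reflect the planted effect sizes, not expected
  clinical performance.
- Peak areas are quantified over the half-height support (~76% of a
  Gaussian's mass); ratios between classes are unaffected.
- The permutation-sampling Shapley estimator is O(perms × features × model
  evaluations) and is applied to a capped evaluation subset by default.
- DCA areas depend on the threshold grid; the grid is a package convention
  and should be held fixed when comparing models.
- The reference biomarker table contains one internally inconsistent row
  (a printed length of 53 against a 49-residue printed sequence); the
  package flags rather than resolves it, and tolerance-based mass matching
  is used because observed MALDI masses in such tables mix conventions.
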