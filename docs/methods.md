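# Methods

`psgrank` benchmarks filter feature-ranking methods and rank aggregation
for five-class sleep-stage classification (W, S1, S2, SWS, REM) from
single-channel EEG, horizontal EOG and submental EMG, sampled at 100 Hz
and scored in 30-s epochs. This note documents the models, the
conventions chosen where a convention was genuinely open, and what the
synthetic cohort does and does not establish.

## Pipeline

1. **Preprocessing.** Epochs whose sum of squares is exactly zero on any
   channel (recording-device dropouts) are removed across all channels
   and the hypnogram; a tolerance is configurable for quantized data.
   EEG and EOG are band-pass filtered to 0.3–35 Hz by wavelet multi-level
   decomposition/reconstruction (db20): decompose to the depth whose
   approximation band falls below the low cut (depth 8 at 100 Hz,
   approximation ≈ 0–0.195 Hz), zero the approximation, zero every detail
   level whose band lies predominantly above the high cut, reconstruct.
   Half-band splits cannot place a cut exactly at 35 Hz; the level-1
   detail (25–50 Hz) is zeroed because more than half of its band lies in
   the stop band — this guarantees ≥ 20 dB suppression above the cut at
   the cost of pass-band loss in 25–35 Hz, where sleep-EEG energy is
   minimal. A level straddling the *low* cut is retained (fidelity
   favored where there is no energy to reject). Band edges are
   config-exposed. EMG is not band-pass filtered.
2. **Feature extraction.** 49 features per epoch (F1–F49): EEG
   statistics, zero-crossing rate, Hjorth parameters, 14 wavelet-packet
   features, four entropies, Petrosian fractal dimension, Teager energy,
   energy, curve length, Hurst exponent, Itakura spectral distance to a
   per-subject wake AR model; EOG amplitude statistics and energy; EMG
   spectral features, energy, and energy ratios to the neighbouring
   epochs.
3. **Standardization.** Each column is scaled to zero mean and unit
   variance with the population (divide-by-n) standard deviation;
   constant columns map to zero.
4. **Balanced sampling.** The same number of epochs (default 100) is
   drawn from every subject, per-stage counts proportional to that
   subject's stage frequencies (largest-remainder rounding, canonical
   stage-order tie-break), without replacement. This balanced table is
   the training set of the whole comparison.
5. **Ranking.** ReliefF, Fisher score, Chi², information gain, CMIM,
   MRMR-MID and MRMR-MIQ each produce a full ordering; Borda and robust
   rank aggregation (RRA) combine the seven into two more.
6. **Evaluation.** Bootstrap stability, pairwise top-d similarity, and
   repeated random sub-sampling accuracy with 1-NN and an LM-trained
   feed-forward net, plus Kneedle selection of the optimal feature count.

## Feature conventions

Where the defining formulas leave parameters or degenerate cases open,
the package fixes them as follows (all config-exposed via
`FeatureConfig`):

- **Statistics:** biased (population) moments; raw, non-excess kurtosis;
  skewness and kurtosis of a constant epoch are 0.
- **Hjorth:** with σₖ the variance of the k-th difference, activity =
  σ₀, mobility = √(σ₁/σ₀), complexity = √(σ₂/σ₁)/√(σ₁/σ₀) — the
  canonical definitions (a pure sine of angular frequency ω has mobility
  ≈ ω and complexity ≈ 1; white noise has complexity > 1). Zero-variance
  epochs map to (0, 0, 0).
- **Wavelet packets:** depth 7, db20, 128 frequency-ordered leaves of
  ≈ 0.39 Hz at fs = 100. Band edges: δ 0.39–3.91, θ 3.91–8.20,
  α 8.20–12.89, spindle 11.72–14.06, β1 12.89–21.88, β2 21.88–35.16 Hz.
  Band energy is the summed squared coefficients over the band's leaves;
  the five ratios are α/(δ+θ), δ/(α+θ), θ/(α+δ), δ/θ, α/θ, a zero
  denominator giving 0 with a warning; the coefficient mean/SD pool the
  six bands' coefficients.
- **Spectral entropy:** Hann-window periodogram restricted to
  0.3–35 Hz (the filter band), normalized to a probability vector,
  Shannon entropy divided by log of the bin count; all-zero spectra give 0.
- **Rényi entropy:** order α = 2 (collision entropy, common in EEG
  work), 16-bin equal-width amplitude histogram over the epoch range.
- **Approximate entropy:** m = 2, r = 0.2·SD (field-standard defaults),
  Chebyshev distance with ≤ r inclusive and self-matches counted;
  computed as Φᵐ(r) − Φᵐ⁺¹(r). The printed-difference variant that
  re-uses length-m counts in both averages is selectable
  (`apen_literal`) but is a documented typo reading, not the default.
- **Permutation entropy:** Bandt–Pompe, m = 3 samples per window, delay
  1, ties resolved by order of appearance (stable sort), natural log.
- **Hurst exponent:** single-window rescaled range over the
  mean-centered epoch, H = log(R/S)/log(N). A regression-over-dyadic-
  windows variant exists behind `hurst_regression` but the single-ratio
  form is the default because the defining expression is one ratio.
- **Itakura spectral distance:** per subject, AR(8) models (Yule–Walker
  with biased autocovariances) are fitted to a seeded random half of the
  wake epochs and averaged elementwise into a reference model. For an
  epoch with fitted coefficients a_test, the distance is
  d = log((a_testᵀ R_ref a_test)/(a_refᵀ R_ref a_ref)) with a = [1, −a₁,
  …, −a_p] and R_ref the exact autocorrelation matrix implied by the
  reference model (solved from the Yule–Walker linear system). This is
  the classical Itakura distance from speech processing; it is ≥ 0
  because the reference coefficients minimize their own process's
  prediction-error quadratic form. All epochs (including the model-fit
  half of wake) receive the feature.
- **EMG energy ratios:** boundary epochs (no previous/next neighbour)
  and zero neighbour energy give ratio 1.

## Ranking conventions

- Chi², IG, CMIM and MRMR operate on 10 equal-width bins over each
  (standardized) column, top bin right-closed; equal-width was preferred
  to quantile binning for transparency, and the count is config-exposed.
- Mutual information is the plug-in estimate with natural logarithms.
- ReliefF: k = 10 neighbours, every instance an update anchor (no
  sampling, hence deterministic), Manhattan distances, per-feature
  contributions normalized by the feature's range, miss contributions
  weighted by class priors renormalized over non-target classes. A class
  with ≤ k members is an error (use a smaller k).
- Ties everywhere break by ascending feature index; Fisher and MIQ use
  an ε = 1e-12 denominator guard.
- Borda points are N − position + 1 summed over methods, best-first
  descending (order-equivalent to ascending raw rank sums). RRA uses
  exact beta order-statistic probabilities: ρ = min_k P(Beta(k, m−k+1) ≤
  r₍ₖ₎) over the sorted normalized ranks, with the Bonferroni-corrected
  min(1, ρ·m) reported as the score; features are ordered by the
  uncorrected ρ so the clipping cannot tie the tail of the list.

## Evaluation conventions

- **Stability:** 50 classical bootstrap replicates (sample n rows with
  replacement) of the balanced table, re-standardized per replicate;
  stability at subset size d is the mean Tanimoto overlap of top-d sets
  over all pairs; d = 1, 3, …, 29. A data-independent ranking scores
  exactly 1. The benchmark shares one replicate set across all nine
  methods (aggregates are recomputed per replicate from the seven base
  rankings).
- **Similarity:** Tanimoto overlap of top-29 sets of the nine methods on
  the full balanced table.
- **Accuracy:** stratified 70/30 repeated random sub-sampling (the split
  fraction is a package default; 200 runs by default, reducible in
  config), 1-NN with Euclidean distance, and a 12-hidden-unit sigmoid
  network with linear one-hot outputs trained by Levenberg–Marquardt
  (damped Gauss–Newton on the residual Jacobian, λ adapted by
  factor-of-10 steps) with early stopping on a 15% validation split of
  each training fold. Weight initialization and splits derive from the
  run seed, so runs are bit-reproducible. A run whose test fold contains
  a class absent from training, or whose training diverges, is logged
  and re-drawn up to a retry cap.
- **Kneedle:** both axes min-max normalized, difference curve y − x,
  knee declared at a local maximum when the curve later drops below that
  maximum minus S·mean(Δx) (S = 1) before the next local maximum;
  several knees → the smallest d (compactness favored); no knee → the
  difference-curve maximum with a warning. Accuracy is scanned over
  d = 1, 3, …, 15.

## The synthetic cohort

The generator emulates what the downstream pipeline needs to be tested
against, not sleep physiology:

- **EEG** is a sum of independent 4th-order-Butterworth band-limited
  Gaussian noise processes (δ 0.3–4, θ 4–8, α 8–13, β 13–30 Hz), each
  normalized to a prescribed share of epoch power, plus broadband noise
  20 dB down. S2 epochs add Poisson-counted 1-s Hann-windowed 13-Hz
  bursts (spindles).
- **EOG** is sub-1-Hz filtered noise (slow rolling movements) plus
  smoothed step deflections whose rate and amplitude scale with the
  stage's eye-movement activity; **EMG** is white noise scaled by the
  stage's muscle tone.
- Stage profiles: alpha-rich wake with high tone; mixed-frequency S1 and
  REM distinguished by atonia and rapid eye movements; spindle-bearing
  S2; strongly delta-dominant SWS with low tone.
- **Within-stage variability:** per epoch, the band-power mix is
  resampled from a Dirichlet centered on the stage profile
  (concentration 25) and the EEG/EMG/EOG amplitudes are modulated by
  log-normal factors (σ = 0.25/0.5/0.5). Real stages overlap in every
  single feature; without this overlap one feature would separate all
  five stages and the ranking comparison would be vacuous. The 50-epoch
  average band powers still match the stage profile.
- **Hypnograms** arrange exact per-stage epoch counts (defaults at
  overnight-recording magnitudes, ≈ 650–1050 epochs per subject across
  six subjects) with a first-order Markov chain (self-transition 0.9)
  that is cosmetic, not physiological.
- The **feature-table generator** plants known structure for ranker
  tests: informative unit-variance Gaussian columns with
  class-conditional means separated by `effect` SDs (level-to-class
  assignment permuted per column), redundant columns as noisy linear
  copies of informative parents (default noise 0.5 SD, correlation ≈ 0.9
  — a *derived* feature, not a near-exact duplicate), and
  class-independent noise columns.

**What passing tests show — and don't.** On this cohort the pipeline
demonstrates internal correctness (formula-level agreement with
independent transcriptions, recovery of planted structure, calibrated
stability, determinism) and the qualitative behaviours expected of the
protocol: accuracy rising with d and plateauing, knees at small d,
redundant features demoted by redundancy-aware rankers. It does not
establish which ranker is best on recorded polysomnography: real EEG has
artifacts, non-stationarity, inter-subject covariance structure and
label noise that the generator deliberately omits. Numbers from the
synthetic benchmark characterize the software, not sleep data.

## Problem sizes

Default problem sizes were chosen so the full benchmark runs comfortably
on a single core: six subjects at overnight-scale epoch counts
(≈ 5 500 epochs extracted), a 100-epoch quota per subject (600-row
analysis table), 50 bootstrap replicates, 20 validation runs in the
shipped acceptance configuration (200 by default in the library), the
d-grids above, and LM training capped at 30 iterations with patience 5.
All are config fields.

## Known limitations

- The wavelet band-pass loses pass-band energy in 25–35 Hz (see above).
- The MI-based rankers' plug-in estimates are biased upward at small
  cell counts; orderings on small tables can differ from asymptotic
  behaviour (the bias affects all candidate features alike).
- ReliefF is O(n²) in the table rows; intended for the balanced
  analysis table, not full-night tables.
- The stage-transition model and signal synthesis are not physiological;
  see above.
- Patient-wise cross-validation and wrapper/embedded selectors are out
  of scope.
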