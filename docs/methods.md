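# Methods

## Study design being emulated

The pipeline targets a film-viewing affect protocol: each of 33 subjects
watches four emotion-eliciting clips — amusement (67 s), tenderness
(99 s), anger (73 s), fear (92 s) — each preceded by a 40-s eyes-open
resting baseline, with 31-channel 10/20-system EEG (FPZ … O2) and
post-clip 9-point ratings (SAM: arousal, valence, liking, familiarity,
dominance; plus per-emotion intensity scores for the four target
emotions). The working sampling rate is 500 Hz. Because no such recordings
are publicly deposited, the cohort is synthesized; every downstream claim
the test suite makes is therefore a *recovery* claim (the pipeline
retrieves what the generator planted), not a claim about human EEG.

## Synthetic cohort model

Each channel of each segment is a sum over the three analysis bands of a
band-limited noise component plus a broadband floor. Band components are
built by inverse-FFT spectrum shaping: flat magnitude on the rFFT bins
inside the band, i.i.d. uniform phases per channel, rescaled so the
sample variance equals the planted target exactly. The parameterization
is sinusoid-equivalent: a band of "amplitude" *a* µV carries variance
*a*²/2 µV².

Planted structure, all configurable (`SynthConfig`):

- **Base amplitudes** per band: θ 5, α 7, β 3 µV — ordered like typical
  resting spectra (α dominant, β weakest).
- **Between-subject heterogeneity**: one multiplicative log-normal factor
  per subject (σ = 0.2 on the log scale). Absolute EEG power is strictly
  positive and right-skewed, so a multiplicative spread is the natural
  stand-in; baseline normalization cancels it exactly, which is the point
  of that normalization.
- **Emotion effects**: multiplicative amplitude factors on named channel
  groups. Defaults encode only effect *directions* — tenderness >
  amusement in right-frontal (FP2, F4) θ/α and midline α/β; fear > anger
  in right-frontal and midline θ — at magnitude 1.3. The magnitude is a
  free generator parameter, not an empirical estimate.
- **Spectral guard band**: planted energy stays 1 Hz clear of each band
  edge (quartered for narrow bands). The analysis taper (2-s Hann,
  0.5-Hz bins) smears energy ±1 Hz; without the guard, edge energy leaks
  across band boundaries and biases the β estimate by ~20%. With it,
  estimated band powers match planted variances to <5% on 60-s segments,
  which is the calibration the test suite asserts.
- **Ratings**: rounded, clipped Gaussians with per-condition means/SDs
  matching the published subjective-assessment table (e.g. anger valence
  1.09 ± 0.29). Non-target emotion scores default to 2.0 ± 1.0. Hit
  forcing (default on) caps non-target scores one point below the target
  score, emulating clips validated at a 100% hit rate.
- One eyes-open baseline per film (8 segments/subject) by default,
  matching per-film baseline normalization; a shared single baseline
  (5 segments) is available via `baseline_per_film=False`.

What the generator does **not** model: volume conduction and channel
covariance (channels are phase-independent), ocular/muscle artifacts,
event-related dynamics, non-stationarity within a clip, and
between-subject variability in *effect expression* (effects are planted
with exact variances, so synthetic effect sizes are far larger than real
EEG effect sizes). Consequently a passing suite demonstrates correctness
of the computations and sign-recovery of planted structure — not
real-data classification performance.

## Preprocessing and spectral estimation

- Zero-phase Butterworth band-pass 1–35 Hz, order 5 per edge, applied
  forward–backward (`sosfiltfilt`). Order 5 keeps a 50-Hz tone below 5%
  residual amplitude after the two passes; phase distortion is zero by
  construction.
- Mastoid re-referencing subtracts the mean of the named reference
  channels; synthetic cohorts carry none, so the step warns and passes
  through (the generator emits already-referenced scalp signals — mastoid
  signals cannot be meaningfully synthesized without head modeling).
- Epochs: 2-s windows, 50% overlap, trailing partial window dropped.
  Artifact rejection removes any epoch with |sample| > 100 µV (per-subject
  configurable); condition power is the average over surviving epochs
  only, and the kept fraction is carried on the epoch set.
- Band power: per-epoch Hann periodogram (window-power compensated,
  density scaling), PSD averaged across epochs, integrated over the
  half-open band [lo, hi) — mean in-band PSD × bandwidth. Integrated
  power satisfies Parseval (a 10-Hz tone of amplitude *a* returns
  *a*²/2 in α) and gives flat-spectrum inputs a θ:β ratio equal to the
  4:17 bandwidth ratio. Half-open bands put 8 Hz in α only.
- Normalization: division by the across-scalp mean baseline power of the
  same subject and band; N = |scalp set| (31 for the default layout) and
  is recorded in run metadata. The operation is scale-invariant and maps
  power equal to the baseline mean to exactly 1.

## Feature bookkeeping

The whole-scalp feature set uses 25 electrodes — the conventional 26-label
list minus PZ, which belongs to the midline set — so 3 × 25 = 75 holds and
the midline block stays disjoint. Widths: 75 / 90 (+15 midline) / 79
(+4 asymmetries) / 94 (+19) / 19. Features default to baseline-normalized
powers; absolute powers are a switch (`value="absolute"`).

## Statistics

- Paired t: two-sided; both d_z = mean(d)/sd(d) and
  d_av = mean(d)/((sd_x+sd_y)/2) are attached because published effect
  sizes are computed either way; d_z is the default report.
- 2×2 fully-within interaction: one-sample test on the per-subject double
  difference; univariately F = t² on (1, n−1); with two bands jointly, a
  Hotelling T² with Wilks λ = 1/(1+T²/(n−1)) and exact
  F = ((n−p)/p)·T²/(n−1) on (p, n−p). Sphericity corrections are
  identities for two-level factors. Both forms are oracle-checked against
  pingouin to 6 decimals. All double differences identically zero returns
  T² = 0, λ = 1; a singular covariance otherwise is an error.
- Partial correlation: residual-based Pearson r, df = n − #covariates − 2.
- BH-FDR via statsmodels step-up. Note: step-up adjustment is not
  idempotent in general; the tested invariants are adjusted ≥ raw, ≤ 1,
  and order preservation.
- Stepwise regression: forward entry at p < 0.05, backward removal at
  p > 0.10 (conventional defaults; thresholds configurable,
  p_enter > p_remove rejected to prevent cycling), iteration guard at
  4 × #candidates. A constant response short-circuits to the
  intercept-only model. Reports B, SE, standardized β, adjusted R²,
  overall F.
- The battery's regression/correlation stage pools all subject × film
  rows (n = 132 at full scale), using the 19 new features as candidates,
  with arousal, valence and familiarity partialled out of the
  liking/dominance correlations and FDR applied per DV family.

## Sparse LDA and classification

SLDA is implemented as elastic-net-penalized optimal scoring: alternate
(i) an elastic-net regression of the scored class indicator on the
z-scored features (sklearn coordinate descent; deterministic) and (ii) a
class-score update D-orthogonalized against previous scores and the
trivial constant score, for K−1 discriminant vectors. Defaults
l1 = l2 = 0.01, 50 alternations max, tol 1e-6; score vectors are
initialized from fixed indicator contrasts so results are reproducible
without a RNG. Features are ranked by the largest |coefficient| across
vectors, ties broken by column order; with penalties → 0 the first
direction matches classical Fisher LDA (tested, |r| > 0.99).

LOSO evaluation: one fold per subject; standardization, SLDA ranking and
the linear SVM (C = 1) are fitted on training subjects only. Default
feature count is the full sparse support (fixed top-k override
available); an empty support falls back to all features. The report
carries per-fold model digests (selected features + SVM coefficients) so
leakage is testable: corrupting a held-out subject's features must not
change that subject's fold model. Binary tasks at full scale have 33
folds × 2 held-out instances; a training fold losing a class is an error.
No kernel or hyperparameter search is attempted — small-n/high-p linear
SVM is the conventional choice in affective EEG.

## Problem sizes in the test suite

Unit and property tests run reduced cohorts (4–12 subjects, 6–12-s
segments, 250 Hz) chosen so the whole suite stays in a few minutes while
each check retains its statistical resolution; the calibration,
direction-recovery (2,000 subjects, 60-s films) and type-I/power
(2,000 replicates, n = 33) checks run at the sizes their tolerances
require. One end-to-end test exercises the full study-scale default
(33 subjects, clip-length films, 500 Hz), which completes in ~1.5 min.

## Known limitations

- No EDF I/O: cohorts interchange as a JSON manifest plus per-segment
  float32 arrays and CSV ratings.
- No ICA/regression ocular correction; artifact handling is amplitude
  thresholding only.
- Classification accuracies on synthetic cohorts reflect planted effect
  magnitudes and are not comparable to human-data accuracies.
- The generator's distributions are stand-ins; no distributional model of
  the original recordings exists to fit against.
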