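# Methods

## Problem setting

Remote photoplethysmography (rPPG) infers cardiovascular quantities from
the minute color fluctuations of facial skin captured by an ordinary
camera. A contactless blood-pressure / hemoglobin estimator built on rPPG
is evaluated the same way a cuff device is: paired readings against a
clinical reference, summarized by agreement statistics and by the
ANSI/AAMI/ISO 81060-2 acceptance criteria. This package implements that
entire workflow — data generation, preprocessing, imbalance-aware
regression, and validation statistics — as a single seeded pipeline.

Because facial video is identifiable, no real recordings ship with the
package; the synthetic generator is a first-class module whose role is to
pose a *controllable inverse problem* with the same statistical structure
a clinic cohort would have.

## Synthetic cohort and signal model

Cohort defaults describe a 200-patient preoperative population: SBP
truncated-normal with mean 127.57 mm Hg on [84.5, 191]; DBP mean
75.17 mm Hg on [54.5, 98]; hemoglobin normal 12.95 (SD 1.81) g/dL; 59%
Monk skin tone 5–6 and the remainder tone 1–4; 38% male; mean age 58.2
(range 21–84); comorbidity flags (hypertension 40%, diabetes 24%, ischemic
heart disease 3%). Only mean and range are published for BP, so the
truncated-normal SD is fixed at (max − min)/6; DBP is redrawn per patient
until it lies strictly below SBP. Two 180-second sessions per patient at
30 Hz share true vitals and heart rate but have independent phase and
noise. 30 Hz is an ordinary webcam rate; it is configurable.

Each of the five facial ROIs (forehead, left/right cheek, nose-and-cheeks,
full face) yields an RGB trace

    trace_c(t) = B_c · tone_factor(MST) + A_c · w(φ(t); τ) + ε_c(t)

with beat phase φ(t) = (HR/60)·t + φ₀ mod 1 and pulse template
`w(u) = exp(−(u−0.2)²/(2·0.1²)) + 0.5·exp(−(u−0.4)/τ)·1[u>0.4]` —
a Gaussian systolic peak plus exponential diastolic tail. The template is
wide enough that the heart-rate fundamental dominates the spectrum, as in
real photoplethysmograms.

The three vital-to-morphology encodings are linear over the physiological
range — the simplest invertible choice, making parameter recovery a fair
test rather than an architecture benchmark:

| encoding | carrier | default mapping |
|---|---|---|
| SBP → systolic amplitude | green amplitude A_G | 0.01·(1 + 1.5·(SBP−84.5)/106.5) |
| DBP → diastolic decay | τ (beat fractions) | 0.08 + 0.15·(DBP−54.5)/43.5 |
| Hb → color ratio | A_R / A_G | 0.5 + 0.8·(Hb−8)/10 |

Blue amplitude is fixed at 0.3·A_G. Monk tone enters only as a baseline
reflectance factor, 1 − 0.6·(tone−1)/9, plus a proportional noise increase
(up to +50% at tone 10); no chromatic skin model is attempted, because the
optics of melanin are outside what this test bed needs to emulate. Noise
is additive white Gaussian (`noise_sd`, default 0.002 on the [0, 1] trace
scale); a configurable fraction of frames is flagged "face not centered"
i.i.d. per frame. All randomness derives from (seed, patient id, session),
so any recording can be regenerated in isolation.

What the generator does *not* emulate — motion artifacts, illumination
drift, autocorrelated sensor noise, BP variation between the two sessions,
within-session vital drift — bounds what passing tests mean: they verify
the pipeline's machinery (windowing, weighting, optimization, statistics)
and the recoverability of cleanly encoded signals, not clinical
performance on real faces.

## Preprocessing

Recordings are cut into consecutive non-overlapping 10-second windows
(180 s → 18 windows; a shorter trailing remainder is dropped), each an
independent data point carrying its patient's reference vitals. Two row
filters follow:

* **quality**: a window is kept iff ≥ 80% of its frames are face-centered
  (the threshold of the original face-tracking software is proprietary;
  0.8 is this package's default and is configurable);
* **extreme labels**: a window is dropped iff SBP ≤ 80 or ≥ 180, or
  DBP ≤ 60 or ≥ 130 mm Hg, boundaries on the drop side. The OR reading
  across vitals is deliberate: requiring *both* vitals out of range would
  retain SBP = 200 with normal DBP, defeating the outlier-removal purpose.
  The conjunction reading remains available via
  `PreprocessConfig(extreme_requires_both=True)`.

The retained windows are shuffled with a seed and split by a fixed
rounding rule — train = ⌊0.70·n⌋, validation = ⌈remainder/2⌉, test = rest —
which at n = 3941 yields exactly 2758/592/591. Window-level shuffling
leaks patients across sets (both sessions and all windows of one patient
can land in different splits); a patient-grouped split mode is provided
for leakage-free evaluation, and the pipeline records which was used.

## Regressor and label distribution smoothing

The regressor input is one window's five ROI × RGB traces stacked as 15
channels of length 300, each channel linearly detrended (removing the
tone-dependent baseline) and scaled by the per-channel training-set SD.
Labels are z-scored by training mean/SD; the transform is inverted at
prediction. The network is a depth-3 1-D U-Net: per-level k=3
convolution + ReLU, stride-2 average pooling, nearest-neighbour upsampling
with skip concatenation, global average pooling, linear head; base 16
channels, ≈ 20k parameters — small enough that 300-epoch training on
thousands of windows is desk-scale. The network, exact backpropagation and
Adam are implemented in numpy (float32, single-threaded-deterministic);
gradients are verified against finite differences in the test suite.

Label distribution smoothing addresses imbalanced regression targets: the
label histogram (bin width 1 mm Hg for BP, 0.1 g/dL for Hb) is convolved
with a symmetric triangular kernel of half-width 5 bins (weights ∝
h+1−|offset|, normalized, zero-padded edges), and each training sample is
weighted by the inverse smoothed density of its bin, rescaled to mean one.
Zero-density bins are floored at the smallest positive density before
inversion. The loss is Σwᵢ(ŷᵢ−yᵢ)²/Σwᵢ — normalizing by the weight sum
rather than n keeps the loss scale invariant to weight rescaling. Balanced
labels therefore degenerate exactly to plain MSE. Training runs a fixed
epoch count (default 300, Adam lr 0.001, batch 64, seeded per-epoch
shuffling); early stopping is available but off by default.

## Validation statistics

All computed on paired (predicted, reference) readings:

* MAPE = 100·mean(|ŷ−y|/|y|); paired differences d = ŷ−y summarized by
  mean, sample SD (n−1), and a 1.96·SD/√n CI half-width. A `signed=False`
  flag reports |mean| — some published tables use the absolute convention.
* Bland-Altman: bias = mean(d), limits bias ± 1.96·SD(d); the 1.96
  multiplier is fixed by convention.
* **ISO criterion 1** (per-measurement errors): pass iff |mean| ≤ 5 mm Hg
  and SD ≤ 8 mm Hg. Published tables sometimes show only the SD clause, so
  both clauses are reported separately as well as combined.
* **ISO criterion 2** (per-subject averaged errors): the permissible SD is
  the largest s with Φ((10−m)/s) − Φ((−10−m)/s) ≥ 0.85, solved by
  bisection to 10⁻⁴ with the observed mean rounded to one decimal (the
  precision at which tables print it); this reproduces the canonical
  6.95 (m=0) and 6.30 (m=2.9) thresholds, rather than interpolating the
  standard's printed table. Both per-subject (the standard's definition)
  and per-measurement variants are implemented, since published reports do
  not always state which was used.
* Shapiro-Wilk normality (3 ≤ n ≤ 5000); Wilcoxon signed-rank, two-sided,
  zeros dropped (Wilcoxon's original convention), exact by enumeration
  over all 2ⁿ sign assignments for n ≤ 12 (valid under ties via midranks)
  and normal approximation with tie/continuity correction above.
* ESH blood-pressure grading with grades 2–3 merged and hypotension
  (SBP ≤ 100 and/or DBP ≤ 60) taking precedence — hypotension is a
  separate sampling category in device validation, so it is checked first.
  Cohort composition is assessed against the ISO sampling minimums
  (SBP ≤100/≥140/≥160 at ≥5/20/5%; DBP ≤60/≥85/≥100 at ≥5/20/5%).

## Numerical and design choices

* Stage seeds are derived as `(global_seed·2654435761 + crc32(stage)) mod 2³¹`,
  so stages rerun in isolation reproduce their randomness.
* Bisection brackets [10⁻⁹, hi] with hi doubled until coverage drops below
  0.85; coverage is monotone decreasing in s, so the root is the largest
  feasible SD.
* The histogram grid starts at the minimum label and extends one bin past
  the maximum, keeping every bin right-open.
* Degenerate inputs fail loudly: empty ROI masks, recordings shorter than
  one window (empty result + warning), all-zero smoothed density, constant
  samples for Shapiro-Wilk, |mean error| ≥ 10 for the criterion-2 solver.
* Numeric outputs are serialized at full precision; rounding to two
  decimals happens only at report rendering.

## Problem sizes used in the test suite

Tests exercise the pipeline at sizes chosen to keep the full suite at
desk scale while leaving each property measurable: parameter recovery uses
60 patients × two 60-second sessions (≈ 700 windows) with noise_sd 0.001
and 50 epochs, reaching median held-out MAPE < 5% per vital over 3 seeds;
the LDS tail-error comparison uses 80 patients with the SBP location
parameter at 105 mm Hg (right-skewed labels, sparse ≥ 130 mm Hg tail),
noise_sd 0.006 and 40 epochs; the noise-degradation property uses 24
patients over a (0.001, 0.008, 0.03) noise grid, all three levels below
the error ceiling at which the model collapses to predicting the cohort
mean. The statistics modules are
validated against brute-force oracles (naive loops, exhaustive sign-flip
enumeration, closed forms) at exact or machine precision.

## Known limitations

* The synthetic encoding is linear and noise white; real rPPG-to-BP
  mappings are nonlinear, confounded (tone, motion, illumination), and
  drift over time. Recovery results here are a correctness check of the
  pipeline, not evidence of clinical accuracy.
* The U-Net is intentionally small; no hyperparameter search, GPU path, or
  model selection on validation loss is provided.
* Window-level splitting (the default, matching common practice in
  development studies) overstates generalization; use the patient-grouped
  mode for honest subject-level evaluation.
* Criterion 2 is sensitive to how many readings each subject contributes;
  with synthetic windows as "readings" the per-subject averages are far
  more stable than in a two-reading clinical protocol.
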