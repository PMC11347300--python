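# Methods

This note records the scientific and numerical choices behind `pupilgate`:
the task model, the synthetic data generator, the preprocessing and feature
definitions, the statistical layer, the authentication evaluation, and the
known limits of what the synthetic results demonstrate.

## Task model

The RSVP oddball protocol is parameterized by `ParadigmConfig` (all
durations in ms). Defaults: 10 blocks × 5 trials × 10 stimuli, 100 ms
stimulus + 100 ms blank (200 ms onset asynchrony), 2 s inter-trial and 5 s
inter-block intervals, 1 target per trial, 30 s preparation and relaxation
periods. Two timing conventions needed fixing where the protocol
description is ambiguous:

* an inter-trial interval follows **every** trial of a block, including the
  last — this is the only reading under which a block of five 2-s trials
  spans 20 s and the core task 10·20 s + 9·5 s = 245 s;
* the initial fixation cross is part of the preparation period rather than
  a per-trial event (a per-trial cross would break the 245-s total).

Event onsets are expressed on the recording clock (the first stimulus fires
at `preparation_period`), so schedules align directly with simulated
recordings that span `total_duration`. Target positions within a trial are
drawn uniformly from a seeded generator; a schedule is fully reproducible
from (config, seed). Nontarget photograph ids are assigned by seeded
sampling *without* replacement (a stranger seen twice starts becoming
familiar, which would contaminate the nontarget condition); target slots
sample the small familiar-face pool *with* replacement.

## Synthetic cohort generator

Each stimulus adds, per EEG channel, one Gaussian-in-time positive
deflection per component, with defaults:

| component | window (ms) | center (ms) | σ (ms) | target (µV) | nontarget (µV) | subject SD (µV) |
|-----------|------------|-------------|--------|-------------|----------------|------------------|
| P3a | 200–350 | 275 | 30 | 8.0 | 4.0 | 1.0 |
| P3b | 400–490 | 445 | 20 | 7.0 | 3.5 | 1.0 |
| LPP | 530–750 | 640 | 45 | 6.0 | 3.0 | 0.8 |

Per-channel gains (Fz 0.95, Cz 1.05, Pz 1.10, Oz 0.60) encode the
centro-parietal dominance and occipital weakness of the P3 family. The
per-event amplitude is `(condition mean + subject offset) · (1 + 0.10·z)`
and the per-event latency is the center plus 10 ms Gaussian jitter clipped
to the window; both draws are recorded as ground truth. The multiplicative
draw and the subject offset are **shared** between the EEG and pupil
renderings — that shared variance is what makes ERP and ErPR features
correlated across a cohort, as the method requires.

EEG noise is 1/f^β Gaussian (β = 1, SD 10 µV per channel), generated in the
frequency domain. The target averaged epoch (n = 50) therefore keeps
≈ 1.4 µV of residual noise against 4–8 µV deflections: large but not
degenerate effect sizes (Cohen's d ≈ 2–3), matching the magnitude a strong
familiar-face protocol produces.

The pupil is modeled as a sluggish integrator: the same component bumps,
scaled by 0.02 mm/µV, are convolved with a unit-area first-order low-pass
kernel (time constant 500 ms), then added to a 4-mm baseline, a slow 1/f²
drift (SD 0.1 mm), white measurement noise (SD 0.005 mm) and Poisson blinks
(15/min, 200 ms) marked invalid (NaN), never zero. Frame-differencing a
low-passed response recovers bump-like deflections, so the ErPR features
are nontrivially related to — but strongly correlated with — the ERP
features. ErPR feature values are in mm/frame and therefore
scale-dependent; cross-modality comparisons z-score each feature first.

Cohort simulation derives per-subject (schedule, signal) seed pairs
deterministically from a master seed via `numpy.random.SeedSequence`; each
subject gets their own randomized target positions.

## Preprocessing

ERP: resample 2048 → 200 Hz (`scipy.signal.resample_poly`, polyphase
anti-aliasing, line-fit edge padding, output length `round(n·ratio)`), then
a zero-phase 4th-order Butterworth band-pass 0.1–50 Hz applied
forward–backward (`sosfiltfilt`) so peak latencies are not shifted. ErPR:
linear interpolation across blink gaps up to 1 s (longer gaps stay invalid
and any epoch touching them is excluded and counted), then
PSC[i] = d[i] − d[i−1], the PSC sample inheriting the timestamp of sample
*i*. Baseline correction subtracts the per-channel mean over [−200, 0) ms
and is applied to the PSC series itself, not the raw diameter.

Epochs span −200…+800 ms (200 samples at 200 Hz). A nominal "800 ms" epoch
starting 200 ms before onset cannot contain the 530–750 ms LPP window; the
feature windows are the binding constraint, so the epoch extends to
+800 ms. Event-to-sample alignment takes the nearest sample, resolving
exact midpoints to the earlier sample. Consecutive onsets are 200 ms apart
while epochs are 1000 ms long, so epochs overlap by construction; the
overlap contributes a common background to both condition averages.
Manual, inspection-based artifact rejection is not automatable; an optional
absolute-amplitude epoch rejection threshold (off by default) is the
documented stand-in.

The ERP and ErPR paths share one epoch/baseline/average implementation;
only the series fed in differs.

## Features

Within each window, amplitude = max − min of the averaged epoch (≥ 0 by
construction, shift-invariant) and latency = time of the window maximum,
earliest sample on ties. "Peak" means the window argmax of the averaged
waveform, not a local-peak detector — well-defined on monotone segments
(where the latency is the window's last sample). Feature tables order
columns channel-major, window-minor (`Fz_P3a_amp, Fz_P3b_amp, …`); latency
columns are optional and sit beside their amplitude column.

## Statistics

* Paired t-test (two-sided) on per-subject target/nontarget pairs, df =
  n − 1; Cohen's d = mean(diff)/sd(diff) with bands 0.20/0.50/0.80.
  Identical inputs return t = 0, d = 0 with a `zero_variance` flag; a
  nonzero constant shift with zero spread is an error.
* Bonferroni: the per-test threshold is α/n. With amplitude *and* latency
  features the family is 24 ERP + 6 ErPR = 30 tests (α = 0.0017);
  classification uses the 12 + 3 amplitude features only. Threshold
  adjustment is the only correction applied; p-values are reported raw.
* Bland–Altman: d̄, SD of differences, limits d̄ ± 1.96·SD, and the
  proportion of pairs within the limits. Because the qualitative labels
  have no universal thresholds, the category cutoffs are explicit
  configuration: "good" = every pair within the limits, "fairly good"
  ≥ 0.95, else "poor". ERP (µV) and ErPR (mm/frame) features are z-scored
  per feature before differencing; per-channel agreement pools the three
  windows (60-row tables give n = 180 pairs).
* Permutation test: the full stratified-CV protocol is re-run on permuted
  labels; p = (1 + #{permuted ≥ observed}) / (1 + n_permutations). Default
  10 000 permutations; examples and the acceptance script use a reduced
  desk-scale count (199–999), which bounds the smallest reachable p
  accordingly.
* Shapiro–Wilk is available as a reported diagnostic only; it gates
  nothing.

## Authentication evaluation

Positive class = target: FAR = FP/(FP+TN) is impostor acceptance,
FRR = FN/(FN+TP) genuine rejection. Stratified 5-fold CV with a fixed
seed; each fold's pipeline (z-scaler + classifier) is fit on the training
fold only, so no leakage through feature scaling. Confusion counts are
pooled across folds for FAR/FRR (they are count-based quantities); the
headline accuracy is the mean of fold accuracies, with the pooled accuracy
also reported. AUC comes from the pooled out-of-fold decision scores.
Classifier hyperparameters are scikit-learn defaults, recorded into each
report. QDA requires more training samples per class than features, so
12-feature ERP tables need cohorts of ⪆ 16 subjects; the 3-feature ErPR
table has no such constraint.

The trial sweep preprocesses each subject once, then for each *n*
re-averages only the epochs from trials 0…n−1 (one target + nine nontargets
per trial, preserving the 1:9 ratio exactly), rebuilds features and
re-evaluates. Values of *n* outside the task or with no usable epochs are
skipped with a logged warning.

## Problem sizes

Default test and acceptance runs use the full protocol (500 events,
305-s recordings at 2048 Hz EEG / 200 Hz pupil) with 30-subject cohorts
for cohort-level claims, 8–12 subjects for property checks that only need
direction, 2000 replicates for the paired-t type-I calibration (run at the
feature level: under equal templates the statistic reduces to paired
noise), and 199–999 permutations for permutation p-values. A full cohort
analysis takes ~10 s; the acceptance script ~1 min.

## What the synthetic results do and do not show

The simulator reproduces the *structure* of the protocol — event-locked
components in the right windows, target > nontarget amplitudes, a sluggish
correlated pupil response, 1/f EEG noise, blinks — with parameters chosen
once for realism. It does not attempt realistic ocular-artifact
topographies, gaze dynamics, illumination effects on pupil size, or
between-subject variation in waveform shape. Two consequences matter when
reading the numbers:

* Passing tests show the pipeline recovers known ground truth and that the
  analysis behaves correctly (calibrated nulls, correct direction, exact
  arithmetic); they do not certify accuracy levels on human data.
* The simulated pupil channel is *cleaner* relative to its signal than the
  simulated EEG, so ErPR classifiers can reach ceiling and outscore ERP
  ones — on human recordings the ordering is typically reversed. The
  correlation range and agreement category between modalities, and the
  direction and size class of the condition effects, are the meaningful
  comparanda.

Known limitations: single-target-per-trial sweeps only (the 1:9 ratio is
assumed, not generalized); four fixed EEG channels; no re-referencing or
channel interpolation; upsampling unsupported; the latency of overlapping
RSVP responses is only meaningful for the averaged waveform, not per event.
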