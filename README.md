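# pupilgate

Biometric authentication from event-related physiological responses. When a
person views a rapid stream of face photographs in which their *own* familiar
face (the target) is hidden among stranger faces (nontargets), their brain
and their pupil both react more strongly to the target. `pupilgate`
implements the full analysis pipeline for this protocol — for classic EEG
event-related potentials (ERP) and for their camera-only analogue, the
event-related pupillary response (ErPR) — together with a synthetic cohort
simulator that provides recoverable ground truth, so every stage can be
tested without human recordings.

It is intended for researchers in physiological biometrics and cognitive
neuroscience who want a reproducible, end-to-end reference implementation of
the RSVP-oddball authentication analysis: stimulus scheduling, signal
preprocessing, component feature extraction, paired statistics with
agreement analysis, and classifier evaluation with biometric error rates.

## The protocol and the method

**Task.** Rapid serial visual presentation (RSVP): each 2-s trial flashes
10 photographs (100 ms image + 100 ms blank, so onsets are 200 ms apart),
exactly one of which is a familiar face. Five trials per 20-s block, ten
blocks, 245 s of core task; nontarget photographs never repeat.

**Signals.** Four EEG channels (Fz, Cz, Pz, Oz) at 2048 Hz and a pupil
diameter trace at 200 Hz. ERP preprocessing: downsample to 200 Hz,
zero-phase 4th-order Butterworth band-pass 0.1–50 Hz, epoch −200…+800 ms
around each onset, baseline-correct on [−200, 0) ms, average per condition
(50 target and 450 nontarget epochs per subject). ErPR preprocessing:
interpolate blinks, difference the diameter frame-to-frame into the pupil
size change PSC(t) = d(t) − d(t−1), then epoch/baseline/average identically.

**Features.** In each of three post-stimulus windows — P3a (200–350 ms),
P3b (400–490 ms), LPP (530–750 ms) — the *amplitude* is the peak-to-peak
value max−min of the averaged epoch and the *latency* is the time of its
maximum. Four channels × three windows give 12 ERP amplitude features; the
single pupil trace gives 3 ErPR features. A cohort of 30 subjects × two
conditions yields a 60-row feature table.

**Statistics.** Paired t-tests (target vs nontarget) with Cohen's
d = mean(diff)/sd(diff), thresholded at the Bonferroni level α/n (0.05/30 =
0.0017); Pearson correlation and Bland–Altman limits of agreement
(d̄ ± 1.96·SD) between z-scored ERP and ErPR features.

**Authentication.** Five classifiers (linear SVM, QDA, Gaussian naive
Bayes, logistic regression, RBF SVM) under stratified 5-fold
cross-validation with in-fold feature scaling, scored by

    Accuracy % = (TP + TN) / (TP + FN + TN + FP) × 100
    FAR = FP / (FP + TN)        FRR = FN / (FN + TP)

with target = positive class, plus AUC and a label-permutation test. A
trial-count sweep re-averages epochs from only the first *n* trials
(keeping the 1:9 target:nontarget ratio) to chart accuracy against task
length.

## Worked example

`examples/05_authentication.py` simulates the default 30-subject cohort,
runs both modality pipelines and evaluates all five classifiers:

```
modality classifier  accuracy_%  AUC  FAR  FRR
     ERP       LSVM        86.7 0.96 0.10 0.17
     ERP        QDA        95.0 1.00 0.10 0.00
     ERP         NB        93.3 0.96 0.07 0.07
     ERP         LR        91.7 0.96 0.07 0.10
     ERP    RBF-SVM        93.3 0.95 0.10 0.03
    ErPR       LSVM       100.0 1.00 0.00 0.00
    ErPR        QDA       100.0 1.00 0.00 0.00
    ErPR         NB       100.0 1.00 0.00 0.00
    ErPR         LR       100.0 1.00 0.00 0.00
    ErPR    RBF-SVM       100.0 1.00 0.00 0.00

ErPR/QDA label-permutation p-value (199 reps): 0.0050
```

Accuracy is the fold-mean cross-validated accuracy; FAR is the rate at
which an impostor's (nontarget) response is accepted and FRR the rate at
which the genuine user's (target) response is rejected. The permutation
p-value (smallest achievable at 199 permutations is 1/200) says the
separation survives relabelling: it is carried by the features, not by
chance. On this synthetic cohort the pupil modality reaches ceiling because
its simulated measurement noise is small relative to the evoked response;
see `docs/methods.md` for what that does and does not imply about real
recordings.

The other examples cover scheduling (`01`), simulation ground truth (`02`),
preprocessing and features (`03`), paired statistics and ERP↔ErPR agreement
(`04`), and the trial-count sweep (`06`). A thin CLI mirrors the library:
`pupilgate schedule|simulate|features|stats|evaluate|sweep|run`.

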