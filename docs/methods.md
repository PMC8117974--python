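# Methods

## Verification model

The verifier is template matching over phone posteriorgrams. A
posteriorgram row p is a point on the 45-simplex (44 BEEP/ARPAbet phone
classes, alphabetical, plus a final silence class). The local distance
between a template frame and an attempt frame is φ = −log(p_h · p_a),
floored at −log(1e−10) so orthogonal one-hot rows stay finite. Dynamic
time warping minimizes the accumulated φ along a monotone path from (1,1)
to (n,m) with the unweighted symmetric step set {(1,0),(0,1),(1,1)}; the
step set and the normalization are design choices the source material
leaves open:

* **Step set** — the standard symmetric pattern; it makes the accumulated
  cost symmetric in its arguments, which the tests exploit.
* **Normalization** — the decision statistic is accumulated cost ÷ path
  length. Unnormalized costs grow with utterance length, so a single
  threshold across words of 2–6 phones is only meaningful per frame;
  the length-normalized statistic puts calibrated thresholds in the
  ~0.4–1.0 range, the scale on which per-speaker thresholds such as 0.675
  are interpretable.
* **Ties** — a distance exactly equal to the threshold is *incorrect*
  ("less than" is strict), and equal-cost DTW paths are interchangeable:
  only the cost is contractual.

With several templates per word the minimum of the per-template normalized
distances is the statistic; `combination_auc` compares this choice against
first-template, maximum and mean combination by ROC AUC.

## Front-end

30 ms Hamming-windowed frames every 10 ms, zero-padded to a 64 ms (1024
sample) FFT, after whole-signal pre-emphasis with coefficient 0.95.
26 triangular mel filters span 0–8000 Hz; cepstra c1–c12 are retained
(c0 excluded — overall level is carried by the separate log-energy term)
and liftered with the sinusoidal lifter 1 + (L/2)·sin(πn/L), L = 23.
Log-energy is the log of the per-frame sum of squares floored at 1e−10, so
silence produces finite, constant features. Deltas are the usual
regression formula with half-width 2 and replicated-edge padding, applied
to all 13 static features (the delta block therefore includes a
delta-energy term, giving 12 + 1 + 13 = 26 features). Where the exact
filterbank and window were genuinely open, the conventional choices above
were made once and are configurable through `FrameSpec`.

Audio input is strict: mono 16-bit PCM WAV at 16 kHz, everything else
rejected explicitly. Resampling or downmixing clinical audio silently
would change the distances being thresholded.

## Acoustic model contract

Any callable mapping a T×26 `FeatureSequence` to a T×45 `Posteriorgram`
plugs in; rows must land on the simplex (renormalized when the row sum is
within 1e−3 of 1, rejected beyond that). The bundled `MockBandModel` is a
deterministic stand-in: it reconstructs a smoothed log-mel envelope from
the cepstra by inverse DCT, scores one "tone phone" per mel band
(softmax, temperature 2), and routes low-energy frames (< 1e−6 total
energy) to silence. It exists so the audio → features → posteriorgram →
verdict pipeline is exercised end to end with pure-tone synthetic audio;
it is not a speech recognizer.

## Threshold calibration and cross-validation

Calibration sweeps every distinguishable threshold — midpoints between
sorted unique distances plus one point beyond each extreme — and maximizes
Pearson's r between the binary decision and the truth label (accuracy is
available as an alternative). Midpoint grids give the exact argmax with no
grid-resolution artifacts, and the best metric is invariant to monotone
transforms of the distances. Ties break toward the smaller threshold,
which favours fewer false positives — the clinically preferred error
direction, since falsely praising an incorrect naming attempt misleads
therapy. `fixed` mode pools all patients; `adapted` fits one threshold per
patient and errors (naming the patients) when a patient lacks both truth
classes.

Cross-validation uses stratified k-fold (default k = 10) with a seeded
shuffle; the threshold is re-fit on each training split and evaluated on
the held-out fold. Per-fold accuracy, FP, FN, F1 and r are aggregated as
mean, SD, min, max and range. Pearson's r is reported as NaN on folds
where it is undefined rather than silently zero.

## Evaluation and agreement statistics

False-positive and false-negative rates are proportions of *all* items, so
accuracy + FP + FN = 1; "correct" is the positive class for F1. Pearson's
r of two binary vectors is the phi coefficient of the 2×2 table and is
flagged undefined (None) under zero variance.

Gwet's AC1 for two raters and two categories: pa is raw agreement,
pe = 2π(1−π) with π the mean of the raters' category-1 marginals, and
AC1 = (pa − pe)/(1 − pe). The variance is Gwet's item-level linearization
(unconditional, no finite-population correction) and the 95% CI is the
normal approximation — the symmetric-CI convention. The benchmark level on
McHugh's scale (>0.90 Almost Perfect … <0.20 None; boundaries implemented
as half-open cut-points at 0.2/0.4/0.6/0.8/0.9 so the intervals partition
the line) is assigned with 95% certainty: interval membership
probabilities under N(AC1, se²) are cumulated from the strongest level
down and the first level reaching 0.95 is reported. This uses only AC1
and its standard error, which is why the normal approximation (rather
than a bootstrap) is the natural estimator. Cochran's Q for k binary
systems is delegated to statsmodels behind the module surface; for k = 2
it equals the McNemar statistic without continuity correction, checked
numerically in the tests.

## Synthetic data

The generator replicates the study design: 220 target words, 8 patients,
2 healthy templates per word (1760 attempts), words of 2–6 pseudo-phones
at 5–15 frames per phone. A posterior row for phone k is the mixture
w·onehot(k) + (1−w)·uniform with w = c/(c+1) and concentration c = 12 by
default; the mixture form gives closed-form control of expected inner
products (a Dirichlet would not). Attempts add 5% random-simplex frame
noise and, for correct attempts, a per-attempt tempo warp of up to ±30%.
Error categories are rendered structurally: phone substitutions/deletions
(Phonological Error), another word (Other), several words' worth of other
phones (Circumlocution), a short "ah" run (Filler), silence frames
(No Response). Per-patient category mixes cycle through mild / moderate /
severe presets (75% / 55% / 35% correct); real per-patient error
distributions are not published at that granularity, so the presets are
free parameters spanning a plausible clinical range, not estimates.

What this emulates — and does not: the generator reproduces the *decision
geometry* (correct attempts near their templates, error categories
progressively farther) but not real acoustics: no coarticulation, no
speaker variability beyond duration, no recognizer confusion structure.
Categories are therefore nearly separable in DTW distance, and the
end-to-end pipeline reaches ~1.0 cross-validated accuracy where the
original clinical study sits near 0.9. Passing tests show the machinery is
correct and the feasibility claim holds under clean posteriors; they say
nothing about accuracy on real aphasic speech.

## Problem sizes and numerics

The test suite and the acceptance script regenerate all inputs at run
time: the full 1760-attempt replica for structural counts and the
end-to-end check (a few seconds), 500 random instances with n,m ≤ 6 for
the DTW brute-force comparison, n = 400 for the overlapping-distribution
cross-validation (Bayes accuracy Φ(2) ≈ 0.977 by construction), and 200
draws for the category distance-ordering check. All randomness flows
through `numpy.random.default_rng` seeds. Known numeric guards: inner
products floored at 1e−10, energies at 1e−10, posterior row sums
renormalized within 1e−3, and the phi coefficient left undefined rather
than forced to zero under zero variance.

## Limitations

No trained acoustic model ships with the package — the verification method
is model-agnostic and the interface accepts any conforming model, but
reported synthetic accuracies do not transfer to real speech. Utterance
segmentation and voice-activity detection are out of scope (inputs are
assumed to be manually segmented single utterances), as are multi-category
agreement coefficients and post-hoc multiple-comparison procedures.
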