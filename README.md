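# nuva

Template-based spoken-word utterance verification for aphasia naming
therapy.

Anomia — impaired word retrieval — is the most pervasive symptom of
post-stroke aphasia, and picture-naming practice is its standard treatment.
Scoring thousands of naming attempts by hand is the bottleneck; this
package implements an automatic verifier that decides, for each single-word
attempt, whether the patient said the target word. It is aimed at speech
scientists and clinical-NLP researchers who need the full verification,
calibration and agreement machinery without access to clinical recordings.

## Method

An utterance is converted to a **posteriorgram**: a T×45 row-stochastic
matrix of per-frame posterior probabilities over 44 ARPAbet phone classes
(BEEP British English inventory) plus silence. The front-end computes 26
features per 30 ms frame (10 ms hop): 12 liftered MFCCs, log-energy, and 13
deltas. Any acoustic model satisfying the `AcousticModel` contract can
produce the posteriors; a deterministic mock model keyed to mel spectral
bands is bundled.

Given a healthy-speaker template H = (p_h1 … p_hn) and an attempt
A = (p_a1 … p_am), the local distance is the negative log inner product

    φ(i, j) = −log(p_hi · p_aj),

and dynamic time warping finds the monotone path from (1,1) to (n,m)
minimizing the accumulated distance (steps {(1,0),(0,1),(1,1)}). The
decision statistic is the accumulated cost divided by the path length,
minimized over the (typically two) templates per word; the attempt is
*correct* iff that minimum falls strictly below a threshold.

The threshold is calibrated from clinician-labelled distances by an exact
sweep maximizing Pearson's r (the phi coefficient) — pooled over patients
(**fixed**) or per patient (**adapted**) — and its generalization is
assessed by stratified 10-fold cross-validation. Evaluation utilities
include accuracy/FP/FN/F1/r, Gwet's AC1 inter-rater agreement with standard
error and a 95%-certainty benchmark level on McHugh's scale, and Cochran's
Q for comparing systems. A synthetic-study generator replicates the
220-word × 8-patient design across the clinical response taxonomy
(Correct, No Response, Filler, Phonological Error, Circumlocution, Other)
so everything is testable offline.

## Worked example

```python
from nuva import SynthConfig, synth_study, calibrate, cross_validate
from nuva.pipeline import study_distances

study = synth_study(SynthConfig(seed=1))       # 220 words x 8 patients
data = study_distances(study)                  # min DTW distance per attempt
print(calibrate(data, "adapted").summary())
print(cross_validate(data.for_patient("P1"), k=10, seed=17).summary())
```

prints (abridged):

```
Threshold calibration results
=============================================
mode:    adapted
metric:  pearson_r
n obs:   1760
  P1: threshold 0.7811   pearson_r: 1.0000
  P2: threshold 1.0002   pearson_r: 1.0000
  ...
Stratified 10-fold cross-validation (seed 17)
=======================================================
           mean   sd  min  max  range
accuracy    1.0  0.0  1.0  1.0    0.0
...
```

Each patient gets their own decision threshold (here ≈ 0.68–1.02 on the
per-frame distance scale) and the held-out accuracy shows how well that
threshold transfers to unseen attempts — 1.0 here because the synthetic
categories are acoustically well separated.

The same steps are available from the shell via the `nuva` CLI
(`synth`, `verify`, `calibrate`, `crossval`, `evaluate`, `agreement`).

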