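# Methods

## Scope and design

`actifuse` implements a multimodal classifier for ADHD screening in children:
wrist-accelerometer recordings re-encoded as Gramian Angular Field (GAF) image
sequences, a ViT–BiLSTM image-sequence encoder, and four fusion strategies
over the image and clinical-tabular modalities. Everything runs on CPU: the
neural layers are built on a small reverse-mode autodiff engine
(`actifuse.autodiff`) written for exactly the operator set this model needs,
with every vector–Jacobian product validated against central finite
differences in the test suite. The engine computes in float32 by default
(switchable to float64), which keeps desk-scale training in seconds without
affecting any of the closed-form encoding or metric code, which is plain
float64 numpy throughout.

## Signal encoding

* **ENMO.** Activity magnitude is the Euclidean norm of (x, y, z) in g minus
  1 g. Negative values (norm below 1 g) are kept by default — the definition
  is applied literally — with an optional clip at zero, which is common
  accelerometry practice.
* **Windowing.** Default 10 s windows at 100 Hz (1000 samples), grouped five
  consecutive non-overlapping windows per model input. Windows are half-open
  `[start, end)` in 0-based sample indices; trailing windows that cannot fill
  a complete 5-frame sequence are dropped. Both knobs are configuration.
* **PAA.** Each window is reduced to the image side length by piecewise
  aggregate approximation over equal-measure bins; samples straddling a bin
  boundary contribute fractionally, so the window mean is preserved exactly.
* **Normalisation scope.** The min–max map to [−1, 1] is computed per window,
  not per recording: each image then uses its full dynamic range, and the
  encoding is invariant to per-window gain. The cost is that a window of pure
  sensor noise is stretched to full range and becomes texture; the
  class-relevant information that survives is the *shape* of activity within
  the window, not its absolute amplitude.
* **Gramian.** G[i,j] = cos(θ_i + θ_j) with θ = arccos(ṽ). The test suite
  checks this against the algebraically independent form
  ṽṽᵀ − √(1−ṽ²)√(1−ṽ²)ᵀ. The [0, 1] rescale is the fixed affine (G+1)/2
  rather than per-image min–max: deterministic, symmetric-preserving, and
  equal Gramian values map to equal pixel values in every image.
* **Channels.** The model input is 3-channel. The default replicates the
  ENMO-GAF across channels (ENMO is scalar, and replication keeps
  compatibility with 3-channel pretrained backbones); a `per_axis` mode
  builds one GAF per axis instead. PNG export quantises to 8-bit grayscale
  (round(255·pixel), earliest window time at the top row); an NPZ option
  exists where exact round-trips matter.

## Clinical pipeline

SNAP-IV has 26 items rated 0–3: inattention (1–9), hyperactivity/impulsivity
(10–18), oppositional (19–26). Subscale scores are block sums; the total is
the sum of all 26. Totals are Z-scored within the cohort using the sample
standard deviation (denominator n−1; configurable) and rescaled to
T = 10 Z + 50; label = 1 iff T ≥ 55, boundary inclusive. Labels are defined
on the full cohort before splitting — the label is a property of the
participant relative to the study sample — whereas *feature* standardisation
uses training-fold statistics only, and a test asserts held-out rows cannot
influence the stored means and deviations. Missing numerics are imputed by
the column mean, categoricals by the mode (ties to the lowest encoded
category, logged).

**Feature-set decision.** The default tabular feature vector is
demographics-only: sex, age, BMI, grade, health state, diet state, parental
education. All SNAP-IV-derived scores are excluded — not just the total. The
label is a deterministic threshold on the total and the subscales sum to the
total, so admitting any of them leaks the label into the features: a model
with subscale features scores far above chance even on a cohort whose
activity and questionnaire generators carry no class signal at all. Users
who want the questionnaire scores as predictors (a defensible choice when
the deployment-time questionnaire is cheaper than the labelling protocol)
can opt in via `feature_columns`.

## Synthetic cohort generator

The generator emulates the study conditions: 50 children, 26% prevalence
(exactly round(0.26·50) = 13 positives), 100 Hz, ages 7–13, BMI ≈ 16.6 ± 2.7,
29/21 male/female, school grades and socioeconomic indicators drawn with the
study cohort's proportions. Movement is a two-state (rest/active)
Markov-switching process over unit gravity with white axis noise
(σ = 0.01 g); bursts in the active state are Gaussian (σ = 0.15 g at rest→
active rate 0.005/sample, active→rest 0.01/sample). The positive class
multiplies both switching rates and the burst variance by (1 + effect_size)
— faster, stronger, more fragmented movement. `effect_size = 2` is the
default "signal present" condition; 0 is the null. A cap on |ENMO| (6 g)
keeps magnitudes physically plausible for a wrist device.

SNAP-IV items are discretised Gaussians on {0..3} (negative-class item mean
1.0, σ 0.8) with the positive-class mean shifted by `snap_shift` (default
0.8 → ≈ +20 points on the total, ~5 within-class standard deviations). The
cohort label is **not** the generator's class bit: synthetic questionnaires
run through the real scoring/T-score/threshold pipeline, and at the default
shift the derived labels agree with the generator classes for ≥ 90% of
subjects (typically 100%), so the whole labelling protocol is exercised.

Per-subject RNG substreams are keyed by (seed, subject index)
(`SeedSequence(entropy=seed, spawn_key=(i,))`), making cohorts bit-reproducible
and each subject's draw stable under cohort-size changes. Deliberately absent:
circadian structure, device calibration error, non-wear periods, posture
changes, and any correlation between demographics and class. Passing tests on
this generator therefore demonstrate that the pipeline recovers the *kind* of
dynamics signal it is built for — not that it reaches any particular accuracy
on real recordings.

The default desk-scale recording length is 2 minutes per subject (12 windows
→ 2 five-frame sequences per subject, 100 sequences per cohort): long enough
for subject-level aggregation to matter, small enough that the full pipeline
encodes in about a second.

## Encoder and fusion

* **ViT.** Patch embedding by linear projection of non-overlapping patches,
  learned class token and position embeddings, pre-norm transformer blocks
  (MLP ratio 4, GELU), final LayerNorm; the class token of the last layer is
  the frame feature. Study-scale configuration: 224 px, patch 16, depth 12,
  12 heads, 768-d. The `tiny` preset (32 px, patch 8, depth 2, 4 heads, 64-d)
  is what the tests and synthetic experiments train. Pretrained weights can
  be loaded from an NPZ checkpoint; nothing is downloaded, and all tests use
  random initialisation.
* **BiLSTM.** Stacked bidirectional LSTM over the five frame embeddings;
  per-frame tokens are forward⊕backward states (2·hidden wide, 256 at study
  scale), and the pooled sequence vector concatenates the last forward and
  last backward states.
* **Cross-attention.** The clinical vector maps to a single query (W_Q);
  keys/values come from the five frame tokens (W_K, W_V); scaled dot-product
  attention over the tokens yields the fused d_k-vector. As printed, the
  attention formula admits a reading with a single pooled image vector as
  K and V, in which case the softmax is over a singleton and the fusion
  degenerates to V; a `single_token` compatibility mode implements that
  literal reading, while the default uses the five per-frame tokens so the
  attention genuinely weights moments in time. Multi-head splitting of d_k
  (default 4 heads at study scale, 2 in the tiny preset) is supported, with
  heads = 1 giving the plain single-head equation; there is deliberately no
  output projection after the attended values, so the singleton case returns
  V exactly in every head configuration.
* **Baselines.** The three comparison fusions are reasonable reconstructions
  (their reference architectures are not published): `simple_concat` —
  concatenate clinical vector and pooled image vector, linear map to d_k;
  `weighted_sum` — both modalities projected to d_k and mixed by σ(α) with a
  single learnable α (α = 0 ⇒ exact 0.5/0.5); `dual_stream` — independent
  small MLP heads per modality whose class logits are averaged. The first
  two feed the shared dropout+linear classifier head; dual-stream fuses at
  the logit level by construction.

## Training and evaluation

* Focal loss, mean over batch of −w_y (1−p_y)^γ log p_y, with γ = 2 and
  inverse-frequency class weights normalised to mean 1; γ = 0 with unit
  weights is exactly cross-entropy. p_y is clamped at 1e−12.
* AdamW (decoupled weight decay), constant learning rate, no scheduler.
  Study-scale defaults: 20 epochs, lr 1e−4, batch 8, weight decay 1e−5,
  dropout 0.5, seed 42. The tiny preset overrides the optimisation to
  30 epochs at lr 3e−3: the study-scale rate is a fine-tuning rate for a
  pretrained backbone, and a random-initialised network trained for a few
  hundred steps needs a much larger step to move its logits at all (we
  verified the gradient flow analytically and numerically; at 1e−4 the tiny
  model's training loss is simply flat).
* Splits are at the subject level, stratified per class by largest-remainder
  rounding of the 0.55/0.15/0.30 quotas (ties go to the earlier set), so each
  set's positive count is within one of exact proportionality. On the
  50-subject cohort with 13 positives this yields 27/8/15 subjects with
  7/2/4 positives. k-fold plans deal each class round-robin with a rotating
  offset, keeping both per-fold class counts and total fold sizes within one.
* When a validation set exists, the epoch with the lowest validation loss
  (evaluated in eval mode, dropout off) is restored at the end; without one,
  the final weights are kept — train loss under dropout is too noisy to
  select an epoch by.
* Metrics: accuracy, precision, recall, F1, MCC from the confusion table,
  AUC by the trapezoidal rule with tied scores collapsed (equal to the
  midrank Mann–Whitney statistic; asserted to 1e−12 against an independent
  rank-based computation). Zero-denominator cases return 0 with a warning so
  degenerate CV folds still aggregate. Evaluation is reported at both the
  sequence level and the subject level (mean of a subject's sequence
  probabilities, thresholded at 0.5; AUC from the mean probability); the
  subject level is the primary number, since screening decisions are
  per-child.
* Cross-validation trains one model per (fusion kind, fold): the held-out
  fold is the test set and the remaining subjects are split 80/20 stratified
  for train/validation. A failed fold is recorded in the report and skipped;
  the run continues.

## Numerical choices and degenerate inputs

* Constant windows (zero dynamic range) are a degenerate input to min–max
  normalisation and raise, by design, rather than silently producing a
  division by zero; polar encoding clamps values within 1e−9 of ±1 and
  rejects anything further out.
* The SNAP-IV T-score is undefined for a cohort with zero variance in totals
  and raises.
* Focal-loss probability clamp 1e−12; attention softmax uses max-subtraction.
* Determinism: model initialisation, dropout, batch order, the generator and
  the splitters each draw from an explicitly seeded generator; eval-mode
  forward passes are bit-reproducible, and the end-to-end pipeline writes
  identical metrics when re-run with the same configuration and seed.

## Problem sizes in the shipped experiments

The synthetic experiments train the tiny preset on the default 50-subject,
2-minute cohort (100 sequences, 32 px images). The single-split experiment
uses the 27/8/15 subject split; the fusion comparison runs 10-fold
cross-validation for each of the four fusion kinds. These sizes were chosen
so a complete run finishes in minutes on one CPU core while still leaving
enough held-out subjects (15, with 4 positives) for a meaningful
subject-level AUC.

## Known limitations

* The synthetic generator's simplifications (no circadian structure, no
  device noise model, independence of demographics and class) mean results
  on it do not transfer quantitatively to real cohorts.
* At study scale (224 px, ViT-Base) the numpy engine works but is far slower
  than a GPU framework; the package is a reference implementation, not a
  training platform for large backbones.
* Accuracy-type metrics at the 0.5 threshold are less stable than AUC for
  the tiny preset on small cohorts — the ranking is learned well before the
  logits calibrate. Threshold tuning and calibration are out of scope.
* The baseline fusion architectures are reconstructions; their absolute
  performance should not be compared against published numbers.
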