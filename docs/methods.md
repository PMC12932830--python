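# Methods

This note records the scientific and numerical choices behind `arlnet`:
what each stage assumes, which parameters matter, what the phantom
cohort does and does not emulate, and where the design was genuinely
open.

## Phantom cohort

The generator emulates the *structure* of a curated CT screening
cohort — a fixed patient count, a fixed number of 2-D grayscale slices
per patient (default 38), patient-level binary labels with a balanced
class mix, 128×128 pixels — not CT physics. Each image is built from

* a smoothed Gaussian noise texture (σ = 2 px) scaled to a background
  standard deviation of `background_noise_sd` (default 0.06 intensity
  units on the [0, 1] scale) around a base level of 0.55;
* two darker elliptical "lung fields" (intensity −0.25, centers and
  semi-axes jittered per image);
* for cancer images, exactly one bright elliptical nodule: radius drawn
  uniformly from `nodule_radius_range` (default 6–12 px), aspect ratio
  0.85–1.15, random orientation, centered inside a lung field, with its
  intensity raised by `nodule_contrast` (default 0.35). The mask marks
  exactly the ellipse pixels.

One nodule per image keeps IoU and Pointing-Game scoring unambiguous.
Randomness flows through a `SeedSequence` tree (cohort → patient →
image), so cohorts are bit-reproducible and insensitive to generation
order. The background consumes its random draws before any nodule
parameter is sampled, which makes the zero-contrast render of a cancer
image identical to the non-cancer render from the same state — the
property the generator's tests exploit.

What the phantom does **not** have: Hounsfield calibration, 3-D
structure, multiple or subtle nodules, anatomical variability,
scanner noise correlations. Passing tests on phantoms therefore
demonstrate the pipeline's mechanics and directional behavior
(separability grows with contrast, attention localizes bright lesions),
not clinical performance.

## Preprocessing and splitting

Images are bilinearly resized to the working resolution and min-max
normalized per image to [0, 1]; a constant image maps to zeros (the
range contract cannot hold, and zero is the deterministic degenerate
choice). A cohort-level min-max variant is available
(`normalize_intensity_global`) since per-image versus dataset-wide
normalization is a genuine alternative; per-image is the default as the
common CT practice.

Splits operate on patients. Partition sizes come from
floor-then-largest-remainder apportionment of the total patient count
(ties broken train > val > test), after which each partition's quota is
spread over the label classes by a second largest-remainder round (ties
by ascending label; the last partition absorbs the per-class
remainder). This scheme keeps every partition's class mix within one
patient of the cohort mix and reproduces the reference arithmetic
exactly: 160 balanced patients → 112/24/24; 790 → 553/119/118 (the odd
553 cannot be split 50/50, so the train partition is one cancer patient
over parity — stratification to the patient, not below it). Patients
are shuffled within class by the split seed, making the split a pure
function of (manifest, spec).

## Architectures and training

The three classifiers are implemented on a small NumPy layer framework
(`arlnet.nn`) written for this package: im2col convolutions, 2×2 max
pooling (gradient split across tied maxima), inverted dropout, dense
layers, global average pooling, channel and spatial attention, a
parameter-free scaled dot-product token-mixing step, Adam, and binary
cross-entropy on logits. Backward passes are exact (verified against
central differences to ~1e-6 relative error), which is what Grad-CAM
reuses.

The printed backbone parameter counts pin the architectures:

* simple CNN: conv 32 → pool → conv 64 → pool → conv 128 → pool → GAP;
  (9·1+1)·32 + (9·32+1)·64 + (9·64+1)·128 = 320 + 18,496 + 73,856 =
  92,672;
* simplified CoAtNet: three 128-filter convs with pooling and dropout,
  1,280 + 147,584 + 147,584 = 296,448, with the attention step kept
  parameter-free so the count still holds.

The counts force a single input channel and cover the convolutional
stack only; dense heads (128 → 64 → 1, mirroring the attention-fusion
head) are additional. The attention-fusion model uses two parallel
branches (conv 32 → pool → conv 64 → pool each), channel-concatenated
to 128 maps — concatenation chosen over addition as the minimal reading
of "two parallel branches" — then channel attention (squeeze-excite
MLP, reduction 8) followed by spatial attention (7×7 conv on the
stacked channel-mean/max maps), GAP, and the dense head. The 128-dim
GAP output doubles as the deep feature export.

Training uses Adam (lr 1e-3 default; the examples and tests mostly use
2e-3), batch size 64, dropout 0.5, sigmoid output, binary
cross-entropy — 60 epochs by default, 20 for the initial
active-learning model. Inputs in [0, 1] are affinely centered to
[−1, 1] at the model boundary; this is a constant transform (not a
learned layer) that keeps early activations balanced and markedly
speeds up CPU training. Max pooling is 2×2 stride 2 throughout;
convolutions are same-padded, so the counts are padding-independent.

## Feature engineering

The 176-dim fused vector is [25 LBP | 15 GLCM | 3 shape | 5 intensity |
128 deep], in that order.

* **LBP (25).** No standard LBP variant yields exactly 25 values, so
  the plain 8-neighbor radius-1 codes (0–255; bit set when neighbor ≥
  center, so ties count as 1 and a constant image deterministically
  codes 255) are binned into a 25-bin equal-width normalized histogram.
  This is a deliberate, prominently documented reading of the required
  25-value block.
* **GLCM (15).** 32 gray levels (the standard radiomics compromise),
  distance 1, directions 0°/45°/90° (the smallest standard set of
  three), symmetric and normalized; per direction the five properties
  contrast, dissimilarity, homogeneity, energy, correlation.
  Correlation of a constant image is the 0/0 case and is set to 1
  (perfect self-similarity).
* **Shape (3).** Otsu threshold → largest 8-connected component →
  (area, perimeter, compactness = 4πA/P²); parameter-free and
  deterministic, (0, 0, 0) with a warning when no foreground exists.
* **Intensity (5).** Mean, SD, median, Fisher skewness, excess
  kurtosis; zero-variance images return 0 for the moment ratios.
* **Deep (128) and fusion.** All features are standardized with
  statistics fitted on the training images only (zero-variance
  dimensions pass through with SD treated as 1). The standardized deep
  block is then gated per dimension by sigmoid weights trained jointly
  with a small logistic head on the training labels and frozen before
  export — the only training signal available for the "learned" gate.
  Gating bounds every deep feature by the dynamic range of the
  standardized handcrafted features, keeping the early fusion balanced.

## The active-reinforcement loop

A tabular Q-function over continuous 128-dim states is ill-posed, so
the state is a discretization: each standardized feature is clipped to
[−2, 2] and quantized into 4 equal bins, and the bin tuple is hashed
(BLAKE2, 12 bytes) to a stable key. A coarser mode keys on the
predicted probability alone (`state_mode="probability"`); it is used in
the fast tests because it exercises identical loop mechanics at a
fraction of the cost. Remaining loop choices, where no value was
prescribed: entropy threshold 0.3 nats and top-k = 50 % of the
qualifying batch; 10 ε-greedy episodes per batch; 5 retraining epochs
per iteration; the episode terminates at the batch end (bootstrap term
zero), since the episode *is* the batch traversal; greedy ties resolve
to action 0 for reproducibility. Samples below the entropy threshold
are discarded after one pass by default (a recycle flag returns them to
the pool).

The reward compares the agent's label to the model's own prediction,
which is circular by construction: the agent converges to the
classifier's argmax on every visited state (a tested property), so its
value lies in filtering by uncertainty and in the tabular memory across
batches, not in discovering labels the model disagrees with. The
pipeline logs pseudo-label disagreement with phantom ground truth per
iteration so this behavior is measurable; the tests assert it stays
below a fair-coin baseline, not that it vanishes.

## Evaluation

Threshold metrics come from the confusion counts with 0/0 cells
resolved to 0 (explicit, warned) rather than propagating NaN. ROC-AUC
uses the rank (Mann–Whitney) formulation with tie correction and is
tested against exhaustive pair counting; PR-AUC is step-interpolated
average precision; Brier is the mean squared probability error.
Bootstrap CIs are percentile intervals over class-stratified resamples
(default B = 1000). The DeLong test is the fast midrank algorithm;
identical score vectors short-circuit to p = 1. Paired t/Wilcoxon
comparisons operate on per-resample metric series (the pairing unit is
a design choice; stratified bootstrap resamples of the test set are
used where the pipeline needs one). Decision curves report
NB(pt) = TP/N − (FP/N)·pt/(1−pt) with treat-all and treat-none
references; pt = 1 is excluded.

Feature selection: CFS is a greedy forward search on the merit
k·mean|r_cf| / √(k + k(k−1)·mean|r_ff|) with constant features
contributing zero correlation; forest selection ranks by mean
impurity-decrease importance; RFE pairs with a logistic estimator
(coefficient-magnitude ranking, the canonical deterministic choice).
The "Bayesian network" bench entry is Gaussian naive Bayes — an
interpretive stand-in, since no network structure or learning algorithm
is specified anywhere.

## Explainability

Grad-CAM weights each feature map by the spatial mean of the class
logit's gradient, rectifies the weighted sum, upsamples bilinearly and
max-normalizes (an all-zero map stays zero). The target stage is the
last convolutional stage of the backbone; for the attention-fusion
model it is the attended fused maps, i.e. the representation actually
pooled for classification. Continuous heatmaps are binarized by the
top-20 % rule (q = 0.8 over the positive values, configurable) before
IoU; both-empty masks score IoU 1 (perfect agreement on absence).
Pointing-Game ties resolve to the row-major first maximum.

## Problem sizes used by the test suite

The suite runs everything at phantom scale chosen for a single CPU:
unit tests use 32×32 images and ≤ 60-image cohorts; the end-to-end
directional check uses a 40-patient, 6-images-per-patient cohort at
64×64 with nodule contrast 0.5 (an "easy" regime by construction),
20 % of train patients initially labeled, 3 loop iterations of batch
44, and an attention-fusion model trained 8 epochs for localization
scoring. Loop-mechanics tests drive the full 23,940-image pool with a
deterministic mock classifier, which exercises batching, selection and
pool bookkeeping without training cost. These sizes are the package's
own desk-scale study conditions; directional properties (accuracy does
not degrade, pseudo-label noise below a fair coin, Pointing Game ≥ 0.8
on easy phantoms) are asserted, never clinical-scale performance
figures.

## Known limitations

* The NumPy CNN core is CPU-only and float64; it is exact and
  well-tested but slow compared to GPU frameworks, so realistic-scale
  training (tens of thousands of 128×128 images, 60 epochs) is outside
  desk scope.
* The phantom's lesions are bright ellipses; texture-only or
  morphology-only malignancy cues are not represented, so feature-
  selection rankings on phantoms say little about real radiomics.
* The Q-agent's reward is self-referential (see above); the package
  measures, but does not resolve, whether it reduces pseudo-label noise
  relative to entropy-only labeling.
* The 25-bin LBP block and the Gaussian-naive-Bayes bench entry are
  documented interpretations of underspecified requirements.
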