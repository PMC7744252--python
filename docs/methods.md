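# Methods

This note documents the models and procedures implemented in `lesionft`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Network

Each MRI sequence feeds one of two identical pathways: thirteen 3×3
convolutional layers with 64 kernels each, batch normalization and ReLU. The
first two layers are plain convolutions; the remaining eleven are dilated.
The layers are grouped into five blocks of (2, 2, 3, 3, 3); the feature maps
at each block's end — five per pathway — are concatenated on the channel
axis (640 channels at default width) and passed through dropout (rate 0.2),
a 1×1 convolution with 128 kernels (BN + ReLU), dropout again, and a final
1×1 convolution with one kernel per class under a per-pixel softmax.

The receptive field of a stack of stride-1 3×3 convolutions with dilation
rates d_i is `1 + 2·Σ d_i`; the 1×1 head adds nothing. The default dilation
schedule is `[1, 1, 2, 2, 4, 4, 4, 8, 8, 8, 8, 8, 3]` (Σ = 61), chosen so
the analytic receptive field is 123×123 pixels — just under the 128×128
training patch. The schedule is a config field and is recorded in every
checkpoint; the two plain (dilation-1) layers sit in the first block.

All convolutions use zero "same" padding, so the network is fully
convolutional: whole slices of any size are processed at inference without
tiling. Initialization is He-uniform; the initializer consumes a single seeded
random stream in a fixed layer order, so equal seeds give bit-identical
models.

### Head and body

The *head* is exactly the two final 1×1 convolutions (weights and the final
layer's bias). Everything else — all pathway convolutions, every batch-norm
affine parameter and every running statistic, including those of the
128-kernel head layer's own BN — is the *body*. This partition is load-bearing:
patient-specific fine-tuning trains the head only, and the test suite asserts
bit-exact equality of all body arrays after fine-tuning. "Batch norm frozen"
is implemented as both untrainable affine parameters *and* inference-mode
normalization (stored running statistics) during fine-tuning forward passes;
updating running statistics on five-patch pools would silently violate the
freeze contract.

### Numerical engine

No deep-learning framework is used. Convolutions are im2col gathers
(numba-compiled) followed by BLAS GEMMs in float32; batch-norm + ReLU are
fused numba kernels; gradients are hand-derived and verified in the test
suite against an independent layer composition and against finite
differences. For inference the frozen batch norm is folded into the
convolution weights, reducing each layer to one GEMM plus a bias-ReLU sweep.
Adam uses (β₁, β₂, ε) = (0.9, 0.999, 1e-8). Workspaces that are consumed
within a single layer call are shared across layers to keep the training
working set cache-resident.

## Base training

Only lesion-containing slices enter training (class balance); 85% of slices
train and 15% validate. The split is at slice level by default, with a
`split_level: patient` switch for the methodologically cleaner patient-level
split. Each slice contributes a fixed pool of 25 randomly placed patches
(128×128 by default) whose footprint intersects the organ mask — offsets
uniform over all valid positions, so patches overlap. Every minibatch draw
applies a fresh rotation by an angle uniform in [−45°, +45°] (bilinear for
images, nearest-neighbor for labels and weight maps). The loss is pixelwise
categorical cross-entropy with class weights (1 background, 5 lesion),
probabilities clamped at 1e-7. Validation loss is evaluated every
`checkpoint_every` iterations (default 250) on the full validation patch
pool in inference mode, and the checkpoint with the lowest validation loss
is returned (ties: earliest).

## Patient-specific fine-tuning

Same loss, optimizer and learning rate as base training; minibatches of 4;
100 iterations by default (the operating point selected across 50–1000 in
the source experiments). Patches come deterministically from each offered
slice: the four corners of the organ bounding box, clipped to the image, and
one patch centered on the box centroid — five per slice — with the same
online rotation. Adam moments restart from zero at fine-tuning (the
alternative, carrying base-training moments, is not meaningful for a
different objective support).

Slice modes: `all_lesion` (default), `all_organ`, and `k_selected_organ` /
`k_selected_lesion`, which rank candidate slices by |mean organ-pixel
probability − 0.5| under the base model on the baseline scan and keep the k
best (ties toward lower slice index — fixed for determinism).

Confusion weighting (optional) replaces the class weights with a per-pixel
map built from the base model's postprocessed baseline prediction:

- detection scheme — missed lesion objects 5; detected lesions: true-positive
  pixels 2, false-negative pixels 0; false-positive pixels of prediction
  objects that touch (share ≥1 pixel with) a detected lesion 0; stand-alone
  false-positive objects and background 1. A prediction object that touches a
  detected lesion is zeroed as a whole, even where it extends far from the
  lesion — the most literal reading of object connectedness; the ambiguity is
  inherent and noted here.
- segmentation scheme — pixelwise: FP 5, FN 5, TP 2, TN 1.

The map is built on the full 3D volume with full connectivity (26 in 3D;
the operation is dimension-generic and uses 8-connectivity on 2D inputs).

## Postprocessing and metrics

Probability volumes are masked by the organ, thresholded at 0.5 (ties count
as lesion — fixed for determinism), closed with a full 3×3×3 element
(erosion border value 1, so volume borders do not erode), optionally opened
per-slice with a plus-shaped 3×3 element (liver profile; disabled in the
brain profile because one-pixel lesions are real there), re-masked, and
split into 26-connected objects. Re-masking after morphology is a choice:
closing may not reintroduce voxels outside the organ.

Detection is object-level: a true lesion is detected when any predicted
voxel overlaps it; FPC counts prediction objects overlapping no true lesion;
F1 combines object recall with object precision ((n_pred − FPC)/n_pred).
Zero true objects yields a flagged, excluded record rather than an
exception. Segmentation: Dice, absolute volume difference as % of the
annotation volume, and the "modified Hausdorff" implemented as the
95th percentile of the symmetric nearest boundary-voxel distances in
physical millimetres (the WMH-challenge convention; boundary = mask minus
its face-connected erosion). Cohort reporting: median [IQR] + Wilcoxon
signed-rank for detection; mean ± SD + paired t for segmentation; α = 0.01.
Wilcoxon drops zero differences and uses the exact null for n ≤ 25, the
normal approximation with continuity correction above. An optional
size-stratified TPR (`--size-split-cm3`, conventionally 1 cm³) separates
detection of small and large lesions; false positives carry no true size
and are not stratified.

## Monte-Carlo-dropout uncertainty

25 test-time repetitions with dropout active and batch norm frozen; the
per-voxel sample SD (n−1 denominator) of the lesion probability is the
uncertainty map. Detection summary: the mean SD over all voxels of the
detected objects, *voxel-pooled* (large objects weigh more) — the
alternative unweighted per-object mean is a defensible reading, but voxel
pooling is the one implemented and tested. Segmentation summary: the maximum
SD within the organ.

## Synthetic longitudinal cohorts

The generator emulates the data regime the method assumes, not MR physics:

- per patient, one smooth anatomy texture (Gaussian-filtered noise, SD
  `patient_signature_sd` = 0.35) and one lesion contrast (N(0.8, 0.35),
  clipped ≥ 0.35) are drawn once and reused at both timepoints;
- per scan, fresh smooth noise (SD `within_patient_noise_sd` = 0.08), a
  global intensity shift (SD 0.05), and i.i.d. acquisition noise (SD 0.02);
- the organ is an ellipsoid; lesions are Gaussian blobs whose half-maximum
  surface defines the annotation, so mask edges sit on soft partial-volume
  transitions;
- at follow-up the volume is rotated in-plane by up to ±5° (repositioning —
  the motivation for rotation augmentation), lesions rescale by a factor
  uniform in [0.7, 1.4], disappear with probability 0.15, and new lesions
  arrive as Poisson(1.0);
- two "sequences" are distinct nonlinear mappings of the same latent anatomy
  (lesions bright in sequence 1, dark in sequence 2), giving the dual
  pathways genuinely complementary inputs.

Defaults: volumes of 24 slices × 128×128 at (3.0, 1.0, 1.0) mm — the
in-plane size mirrors organ-cropped working resolution — with 2–6 lesions of
2–5 voxel radius per patient, which lands lesion-bearing slices at roughly
half of organ slices (the regime between a liver-like 30% and a brain-like
63%). The appearance parameters were calibrated once so that a cohort-trained
base model is good but visibly imperfect on unseen patients (follow-up Dice
roughly 0.4–0.85) while the baseline scan carries reliable patient-specific
signal; this is the regime in which patient-specific fine-tuning is the
designed remedy, and the spread (`patient_signature_sd` well above
`within_patient_noise_sd`) is enforced as a config invariant. What passing
tests on these phantoms shows is that the pipeline's machinery — training,
freezing, selection, weighting, metrics — behaves as specified and that
fine-tuning exploits within-patient appearance sharing when it exists; it
does not certify clinical performance on real liver or brain MRI, where
appearance drift, registration error and annotation noise are richer than
this model.

## Scaled study sizes

The full-scale defaults (64 kernels, 128×128 patches, 10,000 iterations)
match the published recipe. The repository's own experiments and the
end-to-end test suite run a width-scaled model — 16 kernels/pathway with the
head scaled proportionally to (32, 2), 64×64 patches, 1,500 base iterations,
12 training + 10 test patients on 10×88×88 volumes, 100 fine-tuning
iterations, seeds {1, 2, 3} — sizes chosen so a single CPU reproduces the
fine-tuning benefit in minutes rather than days. Checkpoint cadence is 750
iterations there (two validation evaluations per run).

## Known limitations

- 2D slice-wise processing; no 3D context beyond postprocessing morphology.
- At the desk scales used in the test suite, fine-tuning reliably improves
  follow-up Dice, but the companion effect reported for full-scale models —
  lower Monte-Carlo-dropout SD over detected lesions after fine-tuning — is
  within noise (the fine-tuned model also detects additional borderline,
  high-uncertainty lesions). The package computes the summaries; it does not
  assert that trend.
- The phantom generator's appearance model is piecewise-smooth Gaussian
  texture; it has no motion artefacts, no bias fields, no registration error
  beyond a rigid in-plane rotation.
- Object-level TPR counts each annotation object independently by the >0
  overlap predicate; one prediction blob overlapping two annotation objects
  detects both.
- The loss is pixelwise; an object-level loss tailored to detection is out
  of scope.
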