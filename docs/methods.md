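# Methods

## Problem and model

The package addresses two-stage thymoma screening on chest CT: stage 1
separates healthy scans from scans of thymoma patients; stage 2 separates
benign from malignant thymoma among thymoma patients. The unit of
classification is a *fused patch*: three consecutive mediastinally cropped
slices stacked as channels of one 224×112×3 image. Patch labels inherit
the patient's diagnosis (stage 1 labels every patch of a thymoma patient
"thymoma", with no per-slice lesion annotation), and patch predictions are
lifted to scans and patients by the any-positive rule (stage 1) or a
majority vote (stage 2).

The classifier is a VGG16-style convolutional stack (13 conv layers with
3×3 kernels and ReLU in five stages, each closed by 2×2/stride-2 max
pooling with floor semantics) producing a 7×3×512 feature map from the
224×112 input, followed by tokenization (row-major reshape to 21×512, one
shared 512→256 linear projection per token) and two MLP-Mixer blocks. Each
block applies a token mixer — transpose, then per-channel
layernorm → linear (S→h_s) → GELU → linear (h_s→S) with weights shared
across channels, transpose back, residual add — and a channel mixer — the
same MLP shape per token along the feature axis (C→h_c→C, weights shared
across tokens), residual add. The head is layernorm, global average
pooling over tokens, a 2-unit dense layer and softmax.

### Choices where the design was open

* **Token/feature dimensions.** The tokenization arithmetic (7·3 = 21
  positions, 512→256 projection) fixes S=21, C=256, and that is the
  default; both are configurable, since smaller token grids (e.g. 16×128)
  are plausible for other input geometries.
* **Mixer hidden widths** are nowhere prescribed; defaults are the
  parameter-neutral h_s = S and h_c = C.
* **The normalization DN** inside the mixer MLP is layer normalization
  over the mixed axis, as in the original MLP-Mixer; a final layernorm
  precedes pooling (also as in that architecture), toggleable via
  `ModelConfig(final_norm=False)`.
* **Reshape order** for (7,3,512)→(21,512) is row-major over (row, col),
  stated explicitly because nothing else pins it down.
* **Backbone fine-tuning.** The backbone trains with the rest of the
  network by default (`freeze_backbone=False`). Pretrained weights are not
  bundled; `ModelConfig(weights_path=...)` accepts an `.npz` checkpoint,
  and experiments otherwise use seeded He initialization.
* **Input centering.** Patches in [0,1] are mean-centered (subtract 0.5,
  `ModelConfig.input_mean`) before the conv stack, the analogue of the
  mean-subtraction preprocessing used with pretrained CNNs. Without it,
  zero-padded convolutions produce strong border responses on the nearly
  uniform mediastinal band that contaminate saliency maps.
* **Stage-2 aggregation** has no published rule; the default is a majority
  vote over patch hard labels with ties resolved to malignant (the
  conservative clinical call); `rule="mean_prob"` averages probabilities
  instead.

## Training protocol

The reference configuration (`TrainConfig` defaults) is Adam with learning
rate 1e-4, batch size 64, 100 epochs, categorical cross-entropy, no early
stopping, no class weighting or oversampling. Cross-validation is
stratified by the full three-way patient label (so folds mirror the
120:46:32-style composition even for the stage-1 task) and assigns
*patients*, never slices; `run_fold` re-verifies patient disjointness and
raises a hard `LeakageError` otherwise. Per-fold metrics are combined as
unweighted means across folds.

Metrics are accuracy plus macro-averaged precision/recall/F1: each class
is treated as the positive class in turn and the two per-class values are
averaged. This macro convention is adopted because it is the one that
reproduces published per-fold tables exactly from their printed confusion
counts (e.g. counts 18/5/0/16 give macro precision
(18/23 + 16/16)/2 = 89.13%), which a single-positive-class reading does
not. Ratios with zero denominators are reported as 0 with an `undefined`
flag rather than NaN so fold averaging stays defined; displayed values are
rounded half-up to two decimals, with rounding applied only at the end.

## The phantom generator

Thymoma CT datasets are private, so the test bed is a procedural phantom.
Each slice holds a body ellipse (intensity 0.30) over background 0.05, two
dark lung fields (0.08) and a brighter mediastinal band (0.45) drawn to
coincide exactly with the 3×3-grid crop region — which makes the
label-signal oracle exact: lesion pixels sit on a uniform 0.45 background.
Lesions are bright (band + `lesion_contrast`, default 0.35) ellipsoids
spanning a contiguous slice run with an elliptic through-slice radius
profile. Benign lesions are smooth and homogeneous; malignant lesions get
a harmonically perturbed boundary (amplitude `malignant_irregularity`,
default 0.35) and smooth zero-mean internal texture (±25% of the
contrast), so the subtype task carries a morphological signal rather than
an intensity offset. Additive Gaussian noise (sd 0.02) is applied to every
slice. Intensities live in [0,1]; there is no Hounsfield calibration, dose
or reconstruction physics.

Healthy scans are full-length stacks (36–48 slices by default) while
thymoma scans contain only the lesion-bearing slab (3–6 slices),
emulating the order-of-magnitude healthy:thymoma slice imbalance that
lesion-neighborhood slice selection produces in clinical cohorts; with the
default per-scan lengths and cohort proportions of roughly 120:46:32 the
healthy slice count exceeds the thymoma slice count by more than 10×.

What the phantom does *not* emulate: real anatomical texture and
variability, partial-volume effects, scanner noise spectra, lesions
outside the anterior mediastinum, and co-occurring pathology. Passing the
synthetic experiments therefore shows that the pipeline's machinery —
geometry, leakage-free folding, optimization, aggregation, saliency —
works end to end and can learn a localized contrast/morphology signal; it
says nothing about accuracy on clinical data.

## Scaled experiment sizes

The learning-sanity experiment trains the reduced backbone
(`"small"`: one 3×3 conv per stage with 8/16/32/32/32 channels, same five
pooling stages, 64 mixer channels) on a 24-patient phantom cohort
(12 healthy / 6 benign / 6 malignant, lesion contrast 0.5, 9–15 slices per
healthy scan) for 10 epochs at learning rate 1e-3, batch 16, under 3-fold
patient-level cross-validation. The raised learning rate compensates for
the short schedule; the reference 1e-4/100-epoch protocol remains the
package default. On one held-out fold this yields ≥90% patch accuracy and
zero patient-level false negatives under the any-positive rule; these
numbers are recomputed, not asserted, by `scripts/acceptance.py` and the
acceptance tests.

## Grad-CAM

Saliency uses classic Grad-CAM on the final convolutional map: channel
weights are the spatial mean of the gradient of the *pre-softmax* target
logit (so adding a constant to all logits provably changes nothing — a
tested invariant), the rectified weighted sum is bilinearly upsampled to
224×112 and min-max normalized, and can be re-projected into the crop
region of the full slice for overlays. Localization on phantoms is judged
at the CAM's native resolution: the heatmap lives on a 7×3 grid whose
cells span 32×37 patch pixels, so a *hit* means the footprint of the
argmax cell intersects the lesion mask dilated by 12 px (≈ a third of a
cell, the quantization slack of the grid). The pixel argmax itself can sit
a cell away from a lesion centered on a cell boundary, which is inherent
to CAMs at this depth, not a defect of the classifier. Two further caveats:
global average pooling and token mixing spread the logit gradient almost
uniformly over positions, so the classic channel-weight CAM on this
architecture is a feature-alignment map rather than a sharp attribution,
and its peak placement varies with the training seed; elementwise
rectified gradient-times-activation maps localize more sharply on the
phantom but are deliberately not the default, which stays with the classic
formulation.

## Numerical notes

* All layers carry analytic gradients verified against central finite
  differences; training is deterministic for a fixed seed on a given
  platform (pure numpy, no threading nondeterminism in the reductions
  used).
* Max pooling breaks ties by first occurrence (argmax); remainder rows or
  columns of odd dimensions are dropped, matching floor-division pooling
  arithmetic.
* Grid-crop cell edges use floor division; remainder rows/cols fall in the
  discarded third band, so the geometry is deterministic for any H, W ≥ 3.
* Min-max volume normalization refuses constant volumes with an explicit
  degenerate-input error; the fixed-window mode (level/width) is the
  practical path for real DICOM intensities.
* The quality filter drops slices with intensity standard deviation below
  `min_std` (default 0.01 on the [0,1] scale) — an explicit, configurable
  criterion standing in for unspecified "low-quality frame" removal.
* Triplet fusion requires ≥3 slices and discards the 1–2 slice remainder;
  `⌊n/3⌋` patches per scan is an enforced count law.

## Known limitations

* No GPU path; the full VGG16 backbone trains impractically slowly in
  numpy and is intended for forward passes, checkpoint evaluation, or
  small fine-tuning runs — experiments use the reduced backbone.
* The benign/malignant task on phantoms is driven by boundary
  irregularity and texture; real subtype discrimination involves far
  subtler cues.
* Stage-2 aggregation (majority vote) is a package convention, not a
  published rule.
* DICOM support covers single-series directories with uniform slice
  shapes; multi-series studies and resampling are out of scope.
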