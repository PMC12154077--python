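# Methods

## The classification problem

Alzheimer's disease progresses through stages — cognitively normal
(CN), early and late mild cognitive impairment (EMCI, LMCI), generic
MCI, and AD — that are accompanied by structural brain changes visible
in T2-weighted MRI, most prominently ventricular enlargement and
tissue atrophy.  The package classifies 2D axial slices into these
five stages with a small convolutional network trained from scratch,
after two preprocessing steps that dominate practical performance:
removal of non-brain tissue (skull stripping) and correction of the
severe class imbalance typical of clinical archives.

## Phantom data

Real staged MRI cannot be redistributed, so the package generates
phantoms that preserve the statistical shape of such a dataset while
being fully seeded and label-perfect:

* concentric geometry per slice — black background, a bright skull
  annulus (inner/outer radius 0.40/0.46 of the image side, intensity
  0.95), a tissue disc (radius 0.38, intensity 0.55), and a central
  dark "ventricle" disc (intensity 0.05);
* class-dependent morphology — the ventricle radius fraction is
  (0.00, 0.07, 0.13, 0.19, 0.26) for CN → AD, monotone in severity,
  emulating staged ventricular enlargement;
* per-image jitter of center and radii (±1.5% by default) and
  additive Gaussian noise (σ = 0.02 default, 0 for noise-free
  fixtures), clipped to [0, 1];
* per-image seeds derived as master seed + image index, so a dataset
  is a pure function of (counts, size, seed).

The default radii/intensities were chosen so that (a) Otsu's threshold
separates background from tissue+skull, (b) the annulus disconnects
from the disc under a few pixels of erosion, and (c) a trivial
classifier on central dark-disc area already exceeds 80% accuracy —
the separability floor the test suite asserts, which guarantees the
CNN has learnable signal.  What phantoms do **not** model: MRI physics
(bias fields, k-space artifacts, partial voluming), anatomy beyond one
ventricle-like structure, 3D context, or scanner variation.  Passing
tests on phantoms therefore validates the pipeline's mechanics and
contracts, not clinical performance.

## Skull stripping

Otsu's threshold is computed on a 256-bin histogram spanning the data
range; the cut maximizing the between-class variance is returned as a
bin edge, ties breaking toward the lower threshold (8-bit provenance).
Foreground is `pixel > threshold`.  Morphological cleanup uses a disc
structuring element (default radius 3 px at 224²): erosion disconnects
the skull annulus, the largest 8-connected component keeps the brain,
dilation restores the boundary, and hole filling recovers dark
interior structure (ventricles) into the mask.  The stripped image is
the input multiplied by the mask, exactly zero outside.  On noise-free
phantoms the predicted mask's dice against ground truth exceeds 0.95
(in practice ≈ 0.999); opening with a disc rounds square corners, which
is why the unit tests assert near-identity rather than identity for
box-shaped inputs.

## SMOTEENN

SMOTE grows every class to the majority count (configurable target) by
sampling a base point, one of its k = 5 same-class nearest neighbors
(Euclidean metric on flattened [0, 1] pixels), and a uniform mixing
weight; synthetic rows therefore never leave the per-coordinate
bounding box of their parents, a provenance-tracked invariant.  ENN
then makes a single pass over the combined set using neighbors from the
pre-removal structure: a sample is kept iff at least k/2 of its k = 3
nearest neighbors share its label — exactly the "differs from at least
two of its three nearest neighbors" removal rule — with even-k ties
kept (conservative).  ENN applies to all classes by default, which is
the only way the majority class can shrink; iterated ENN variants are
deliberately not implemented.  Resampling defaults to the training
partition only; a `before-split` placement exists for replicating
whole-dataset usage and logs a leakage warning.

## Architecture and accounting

The mixer stacks conv(5×5, 16) → avgpool → conv(5×5, 32) → avgpool →
sepconv(5×5, 64) → avgpool → sepconv(5×5, 128) → avgpool → dropout 0.5
→ flatten → dense 256 (ReLU) → dense 5 → softmax; all convolutions are
valid-padded, stride 1, ReLU.  Analytic accounting per layer:

* spatial extent `floor((I − F + 2P)/S) + 1`, pooling 2×2 stride 2
  with floor semantics;
* conv parameters `(k_h k_w C_in + 1) F`; separable conv = depthwise
  kernel `k_h k_w C_in` (no bias) + pointwise `C_in F` + one bias `F`;
  dense `(fan_in + 1) units`;
* MACs: conv `o_h o_w F (k_h k_w C_in)`, separable
  `o_h o_w (k_h k_w C_in + C_in F)`, dense `fan_in · units`; a
  `flops2x` convention doubling MACs is also reported.

With a 224×224×3 input the chain is 224 → 220 → 110 → 106 → 53 → 49 →
24 → 20 → 10, flatten 12,800, and the per-layer parameters
1,216 + 12,832 + 2,912 + 9,920 + 3,277,056 + 1,285 = **3,305,221**.
The input is 3-channel (grayscale replicated) because that is the only
channel count consistent with this total; single-channel operation is
configurable.  The four-stage chain needs at least 68 pixels per side,
so desk-scale experiments use a scaled variant of the same structure
(3×3 kernels, 8/16/32/64 filters, dense 64; 21,109 parameters at
64×64×1) — chosen to keep the conv-conv-sep-sep mixer shape while
fitting small phantom images.  Replacing either separable convolution
with a full convolution strictly increases the parameter count
whenever `C_in > 1` and `F > 1`, which is the efficiency claim at the
level where it is exactly testable.

## Weight initialization

Glorot-normal (default), He-normal (truncated normals, ±2 std, std
√(2/(n_in+n_out)) and √(2/n_in)), Glorot-uniform and He-uniform
(bounds √(6/(n_in+n_out)) and √(6/n_in)).  Truncation at two standard
deviations shrinks the delivered variance by the closed-form factor
1 − 4φ(2)/erf(√2) ≈ 0.774, which the statistical tests correct for.
Biases start at zero; initializers apply to kernels only.

## Training

Mini-batch cross-entropy minimization: `L = mean(−Σ_c y_c log p_c)`
with predictions clipped to [1e−7, 1].  Defaults follow the ablation
outcome: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7), learning rate 0.001,
batch 8, glorot-normal, average pooling; Adagrad, Adamax and Nadam are
available for the ablation grid, which trains one model per
initializer × pooling × optimizer cell under a shared seed.  Splits
are stratified with largest-remainder rounding (default 0.8/0.1/0.1 —
train, validation, and a held-out test partition).  No early stopping;
no batch normalization.  All randomness (init, shuffling, dropout)
derives from the config seed, so runs are bit-reproducible.  Desk-scale
experiments use 100 phantoms/class at 64 px for ~10 epochs (seconds to
minutes on one CPU); the full-size architecture accepts the same code
path unchanged.

## Evaluation

One-vs-rest TP/TN/FP/FN come from the 5×5 confusion matrix; accuracy
= trace/total, precision `TP/(TP+FP)` (0 with a logged note when no
positives are predicted), recall `TP/(TP+FN)`, F1 `2TP/(2TP+FP+FN)`;
macro aggregation is the default (the five stages are clinically
symmetric), support-weighted is available; tables print percentages to
two decimals.  ROC curves sweep each class's score column with tied
scores grouped at one threshold; AUC is the trapezoid area, equal to
the Mann–Whitney pair-ordering statistic (ties ½), which the tests
verify; micro and macro aggregates are emitted, with absent classes
excluded from the macro mean.

## Saliency

The map `S = ReLU(Σ_k α_k A_k)` uses activations of the last conv-type
layer (overridable) and `α_k` = spatially averaged gradient of the
**pre-softmax** class score — the logit is used rather than the
probability so that a confident softmax cannot flatten the gradients.
S is bilinearly upsampled to the input grid and max-normalized
(identically zero maps are left at zero with a logged note); overlays
use a jet-style colormap, red = important.

Faithfulness is validated by occlusion: replacing the top-decile
heatmap pixels with the dataset-mean intensity should reduce the
target logit more than replacing an equal number of random pixels.
On skull-stripped phantoms the trained scaled mixer passes this for
essentially all test images.  On *unstripped* phantoms it does not:
the bright, class-uninformative skull ring dominates the
positive-evidence map, and mid-severity stages — whose defining
feature is an intermediate ventricle size, i.e. evidence that is not
purely positive — get near-flat maps.  This is a known structural
limitation of gradient-weighted activation mapping (only
positively-contributing regions survive the ReLU) and is the concrete
argument for skull stripping ahead of explanation in this pipeline.

## Numerical and degenerate-input conventions

* Otsu on a constant image raises (no variance to split); erosion that
  annihilates a mask raises with advice to shrink the radius.
* Dice of two empty masks is 1.0 (vacuous agreement); exactly one
  empty gives 0.0.
* kNN ties break toward the lower index everywhere (stable sorts), so
  resampling is platform-independent.
* SMOTE refuses to grow a singleton class (nothing to interpolate);
  SMOTEENN raises if editing eliminates a class outright.
* Max-pool gradients are split equally among tied maxima.
* ENN with even k keeps on exact ties.
* Image I/O: 8-bit PNGs scale by 1/255, 16-bit by 1/65535; NIfTI
  volumes contribute their middle axial slice min-max normalized;
  unreadable files are skipped with a manifest note.

## Limitations

Phantom realism is deliberately minimal (see above).  Reported
real-data figures from staged-MRI studies are not reproducible without
their images; the package instead pins exact structural quantities
(the 3,305,221-parameter architecture) and behavioral properties at
desk scale.  The NumPy engine is single-threaded per op and intended
for small images and datasets, not production-scale training.  FLOP
totals depend on counting conventions; both MAC and 2×MAC conventions
are printed and neither is asserted against external tool output.
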