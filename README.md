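# stcunet

Renal tumors in abdominal CT are hard to segment automatically: their
boundaries are blurred, and their size, shape and position vary widely.
`stcunet` implements a 2-D U-Net variant for this task that enriches the
network with three attention mechanisms, each placed where its inductive
bias helps most:

* **Selective-kernel (SK) blocks** on the skip connections of the three
  shallow encoder stages.  Each block convolves the map with 3×3, 5×5 and
  7×7 kernels in parallel and mixes the branches with a per-channel softmax
  (split → fuse → select), letting the network pick its receptive field per
  channel where fine detail lives.
* **Non-patch vision-transformer (ViT) blocks** at the two deep stages
  (the stage-4 skip pathway and after the bottleneck convolutions).  Every
  pixel of the small deep feature map is one token — sequence length
  H·W, no patch partitioning — through a standard pre-norm transformer
  encoder, adding global context without discarding pixel-level detail.
* **Coordinate-attention (CA) blocks** after each decoder stage.  Channels
  are pooled separately along height and width and re-weighted by logistic
  gates `y_c(i,j) = x_c(i,j) · g_h_c(i) · g_w_c(j)`, which preserves
  positional information for localization during upsampling.

Training uses the class-imbalance-robust composite loss

    Total = DiceLoss + BCE,   DiceLoss = 1 − (2 Σ yᵢpᵢ + ε) / (Σ (yᵢ+pᵢ) + ε)

and evaluation reports IoU, Dice, Accuracy, Precision, Recall and F1 from
pixel confusion counts, with explicit micro/macro aggregation.

The package is pure NumPy/SciPy — it ships its own compact reverse-mode
autodiff engine — and everything (model blocks, CT preprocessing, training,
evaluation) is exercisable end to end on built-in synthetic CT phantoms, so
no dataset download is required to use or test it.  A KiTS19-style NIfTI
preprocessing chain (windowing, tumor-slice filtering, ROI cropping,
resampling, seeded 8:2 splitting, online augmentation) handles real data
when you have it.

## Worked example

Train the scaled-down model on synthetic phantoms and evaluate it:

```bash
stcunet synth --out phantoms --n 250 --size 96 --seed 7
stcunet train --data phantoms/manifest.csv --out run \
    --variant stc_unet --image-size 96 --base-width 16 \
    --learning-rate 2e-3 --epochs 4 --max-steps 200 --seed 7
```

which prints one record per epoch (total/Dice/BCE training loss and
held-out Dice) and keeps the best checkpoint:

```
[epoch   1] loss=1.4753 (dice 0.9297 / bce 0.5456) val Dice=0.7631
[epoch   2] loss=1.1476 (dice 0.8697 / bce 0.2778) val Dice=0.9365
[epoch   3] loss=0.6770 (dice 0.6117 / bce 0.0654) val Dice=0.8780
[epoch   4] loss=0.2721 (dice 0.2574 / bce 0.0147) val Dice=0.9409
best validation Dice: 0.9409; checkpoint: run/best.npz
```

The loss is the training objective on soft probabilities (averaged over the
epoch), while `val Dice` is the thresholded (0.5), per-image Dice overlap on
the 50 held-out phantoms: after 200 optimizer steps the best epoch overlaps
~94 % of each synthetic tumor (Dice 0.9409).  `stcunet evaluate` reproduces the
full six-metric report for any checkpoint, and `stcunet predict` writes
probability map, binary mask and overlay for a single slice.

Metric reports from two models can be compared in the standard
candidate-minus-baseline form (here: the published KiTS19 table rows for
the baseline U-Net and the attention-augmented model):

```
Method    Iou(%)  Dice(%)  Accuracy(%)  Precision(%)  Recall(%)  F1(%)
unet      95.80   94.92    94.27        97.05         96.18      96.61
stc_unet  97.40   96.94    96.54        98.23         97.70      97.96
delta     +1.60   +2.02    +2.27        +1.18         +1.52      +1.35
```

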