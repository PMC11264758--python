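"""Training loop, evaluation and prediction.

Defaults follow the reference regime for the full-size task: Adam with
learning rate 1e-5, batch size 4, 50 epochs, the composite Dice+BCE loss,
and online augmentation on the training split.  Everything is driven by a
single integer seed that fixes parameter initialization, data shuffling,
augmentation draws and dropout.  Each run writes a line-oriented log, a
per-epoch CSV history and a best-by-validation-Dice checkpoint.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad, sigmoid
from .losses_metrics import (
    MetricsReport,
    compute_metrics,
    confusion_counts,
    total_loss,
)
from .model import ModelConfig, SegmentationModel, build_model, save_checkpoint
from .preprocess import AugmentConfig, SliceSample, augment, load_sample, read_manifest

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "predict_probabilities"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam; no schedule, no weight decay)."""

    learning_rate: float = 1e-5
    batch_size: int = 4
    epochs: int = 50
    max_steps: int | None = None  # cap on total optimizer steps, for smoke runs
    seed: int = 0
    loss_epsilon: float = 1.0
    threshold: float = 0.5
    augment: bool = True
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainResult:
    model: SegmentationModel
    history: list[dict]
    checkpoint: Path | None
    best_dice: float


def _samples_to_arrays(samples: list[SliceSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    masks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return images, masks


def _load_split(manifest, split: str) -> list[SliceSample]:
    rows = [r for r in read_manifest(manifest) if r["split"] == split]
    if not rows:
        raise ValueError(f"manifest has no rows in split {split!r}")
    return [load_sample(r) for r in rows]


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, manifest,
          variant: str = "stc_unet", out_dir=None,
          log=print) -> TrainResult:
    """Train on the manifest's train split; validate on its test split.

    Returns the trained model, the per-epoch history, and (when ``out_dir``
    is given) the path of the best-by-validation-Dice checkpoint.
    """
    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(model_cfg, variant, seed=int(rng.integers(2**31)))
    train_samples = _load_split(manifest, "train")
    val_samples = _load_split(manifest, "test")
    for s in train_samples + val_samples:
        if s.image.shape[0] % 16 or s.image.shape[1] % 16:
            raise ValueError(
                f"slice {s.case_id}/{s.slice_index} has size {s.image.shape}, "
                "not divisible by 16")
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)
    aug_rng = np.random.default_rng(rng.integers(2**31))
    shuffle_rng = np.random.default_rng(rng.integers(2**31))

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "run.json").write_text(json.dumps({
            "variant": variant,
            "model": json.loads(model_cfg.to_json()),
            "train": {k: getattr(train_cfg, k) for k in
                      ("learning_rate", "batch_size", "epochs", "max_steps",
                       "seed", "loss_epsilon", "threshold", "augment")},
            "n_train": len(train_samples), "n_val": len(val_samples),
        }, indent=2))

    history: list[dict] = []
    best_dice = -1.0
    best_path = (out_dir / "best.npz") if out_dir is not None else None
    steps_done = 0
    t0 = time.time()
    for epoch in range(1, train_cfg.epochs + 1):
        model.train()
        order = shuffle_rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            if train_cfg.max_steps is not None and steps_done >= train_cfg.max_steps:
                break
            batch_idx = order[start:start + train_cfg.batch_size]
            batch = [train_samples[i] for i in batch_idx]
            if train_cfg.augment:
                batch = [augment(s, train_cfg.augment_cfg, aug_rng) for s in batch]
            images, masks = _samples_to_arrays(batch)
            logits = model(Tensor(images))
            probs = sigmoid(logits)
            loss = total_loss(probs, masks, epsilon=train_cfg.loss_epsilon)
            opt.zero_grad()
            loss.tensor.backward()
            opt.step()
            steps_done += 1
            epoch_losses.append((loss.total, loss.dice, loss.bce))
        if not epoch_losses:
            break
        report = evaluate_model(model, val_samples, threshold=train_cfg.threshold)
        mean = np.mean(epoch_losses, axis=0)
        record = {
            "epoch": epoch, "steps": steps_done,
            "total_loss": float(mean[0]), "dice_loss": float(mean[1]),
            "bce_loss": float(mean[2]), "val_dice": report.dice,
            "val_iou": report.iou, "seconds": round(time.time() - t0, 2),
        }
        history.append(record)
        log(f"[epoch {epoch:3d}] loss={record['total_loss']:.4f} "
            f"(dice {record['dice_loss']:.4f} / bce {record['bce_loss']:.4f}) "
            f"val Dice={report.dice:.4f}")
        if report.dice > best_dice:
            best_dice = report.dice
            if best_path is not None:
                save_checkpoint(model, best_path, epoch=epoch,
                                val_dice=report.dice, train_seed=train_cfg.seed)
        if train_cfg.max_steps is not None and steps_done >= train_cfg.max_steps:
            break
    if out_dir is not None:
        with open(out_dir / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return TrainResult(model=model, history=history, checkpoint=best_path,
                       best_dice=best_dice)


def predict_probabilities(model: SegmentationModel, images: np.ndarray,
                          batch_size: int = 4) -> np.ndarray:
    """Sigmoid probabilities for a [N, H, W] or [N, 1, H, W] image stack,
    computed in eval mode without building autodiff graphs."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    model.eval()
    outs = []
    with no_grad():
        for start in range(0, arr.shape[0], batch_size):
            logits = model(Tensor(arr[start:start + batch_size]))
            outs.append(sigmoid(logits).data)
    return np.concatenate(outs, axis=0)


def evaluate_model(model: SegmentationModel, samples: list[SliceSample],
                   threshold: float = 0.5,
                   aggregation: str = "macro_per_image") -> MetricsReport:
    """Metrics of a model over a list of slices at the given threshold."""
    images, masks = _samples_to_arrays(samples)
    probs = predict_probabilities(model, images)
    counts = [confusion_counts((probs[i, 0] >= threshold).astype(np.uint8),
                               masks[i, 0].astype(np.uint8))
              for i in range(len(samples))]
    return compute_metrics(counts, aggregation=aggregation)


def evaluate(model: SegmentationModel, manifest, split: str = "test",
             threshold: float = 0.5,
             aggregation: str = "macro_per_image") -> MetricsReport:
    """Evaluate a model on one split of an on-disk dataset manifest."""
    return evaluate_model(model, _load_split(manifest, split),
                          threshold=threshold, aggregation=aggregation)
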