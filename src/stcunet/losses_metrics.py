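"""Composite Dice + binary cross-entropy loss and the six-metric evaluation
suite (IoU, Dice, Accuracy, Precision, Recall, F1) with explicit aggregation
semantics and model-comparison reports.

All six metrics derive from a single pixel confusion matrix (TP, TN, FP, FN):

    IoU       = TP / (FN + FP + TP)
    Dice      = 2 TP / (2 TP + FN + FP)
    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 P R / (P + R)            (= Dice for one confusion matrix)

Two aggregation modes are supported: ``micro_global`` pools pixel counts over
all images first; ``macro_per_image`` averages per-image metric values.  A
report always records which mode produced it.

The training loss is ``Dice Loss + BCE Loss`` with

    Dice Loss = 1 - (2 sum(y p) + eps) / (sum(y + p) + eps)
    BCE Loss  = -(1/N) sum[ y log p + (1 - y) log(1 - p) ]

where ``eps`` (default 1.0) smooths the empty-mask case and probabilities are
clamped away from {0, 1} before the logarithms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "LossValue",
    "dice_loss",
    "dice_coefficient",
    "bce_loss",
    "total_loss",
    "confusion_counts",
    "compute_metrics",
    "f1_from_precision_recall",
    "compare_reports",
    "render_comparison",
    "BCE_CLAMP",
]

BCE_CLAMP = 1e-7

_METRIC_ORDER = ("iou", "dice", "accuracy", "precision", "recall", "f1")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as_prob_tensor(probs) -> tuple[Tensor, bool]:
    if isinstance(probs, Tensor):
        return probs, True
    return Tensor(np.asarray(probs, dtype=np.float64)), False


def _check_shapes(probs: Tensor, target: np.ndarray) -> None:
    if probs.shape != target.shape:
        raise ValueError(
            f"prediction shape {probs.shape} does not match target shape {target.shape}")


def dice_loss(probs, target, epsilon: float = 1.0):
    """1 - smoothed Dice coefficient; differentiable in ``probs``.

    Returns a scalar :class:`Tensor` when given one, else a float.
    """
    p, was_tensor = _as_prob_tensor(probs)
    y = np.asarray(target, dtype=p.dtype)
    _check_shapes(p, y)
    inter = (p * Tensor(y)).sum()
    denom = p.sum() + float(y.sum())
    out = 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    return out if was_tensor else out.item()


def dice_coefficient(probs, target, epsilon: float = 1.0):
    """Smoothed soft Dice overlap; ``dice_loss + dice_coefficient = 1``."""
    out = dice_loss(probs, target, epsilon)
    return 1.0 - out if isinstance(out, float) else 1.0 - out


def bce_loss(probs, target, clamp: float = BCE_CLAMP):
    """Mean binary cross-entropy with probabilities clamped to
    [clamp, 1 - clamp]."""
    p, was_tensor = _as_prob_tensor(probs)
    y = np.asarray(target, dtype=p.dtype)
    _check_shapes(p, y)
    pc = p.clip(clamp, 1.0 - clamp)
    yt = Tensor(y)
    n = float(y.size)
    out = -((yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()).sum()) / n
    return out if was_tensor else out.item()


@dataclass
class LossValue:
    """The two loss parts and their sum; ``total = dice + bce``."""

    dice: float
    bce: float
    total: float
    epsilon: float
    tensor: Tensor | None = None  # differentiable total when inputs were Tensors


def total_loss(probs, target, epsilon: float = 1.0) -> LossValue:
    """Dice Loss + BCE Loss, returned with both parts broken out."""
    p, was_tensor = _as_prob_tensor(probs)
    d = dice_loss(p, target, epsilon)
    b = bce_loss(p, target)
    t = d + b
    return LossValue(dice=float(d.data), bce=float(b.data), total=float(t.data),
                     epsilon=epsilon, tensor=t if was_tensor else None)


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts; the sole source for all six metrics."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion_counts(pred_mask, target) -> ConfusionCounts:
    """Exact TP/TN/FP/FN pixel counts for two binary masks."""
    p = np.asarray(pred_mask)
    y = np.asarray(target)
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {y.shape}")
    for name, a in (("prediction", p), ("target", y)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = p.astype(bool)
    y = y.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & y)),
        tn=int(np.count_nonzero(~p & ~y)),
        fp=int(np.count_nonzero(p & ~y)),
        fn=int(np.count_nonzero(~p & y)),
    )


def _safe_ratio(num: float, den: float, pred_empty: bool, ref_empty: bool) -> float:
    """num/den with the empty-mask convention: an undefined ratio is 1 when
    the reference set is also empty, else 0."""
    if den == 0:
        return 1.0 if ref_empty else 0.0
    return num / den


def _metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    if c.total == 0:
        raise ValueError("confusion counts are all zero — nothing was evaluated")
    target_empty = (c.tp + c.fn) == 0
    pred_empty = (c.tp + c.fp) == 0
    both_empty = target_empty and pred_empty
    iou = _safe_ratio(c.tp, c.fn + c.fp + c.tp, pred_empty, both_empty)
    dice = _safe_ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, pred_empty, both_empty)
    accuracy = (c.tp + c.tn) / c.total
    precision = _safe_ratio(c.tp, c.tp + c.fp, pred_empty, target_empty)
    recall = _safe_ratio(c.tp, c.tp + c.fn, pred_empty, pred_empty)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"iou": iou, "dice": dice, "accuracy": accuracy,
            "precision": precision, "recall": recall, "f1": f1}


@dataclass(frozen=True)
class MetricsReport:
    """The six metrics as fractions in [0, 1] plus the aggregation mode."""

    iou: float
    dice: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    aggregation: str = "macro_per_image"

    def as_percent(self, decimals: int = 2) -> dict[str, float]:
        return {m: round(getattr(self, m) * 100.0, decimals) for m in _METRIC_ORDER}

    @classmethod
    def from_percent(cls, aggregation: str = "macro_per_image", **percent) -> "MetricsReport":
        vals = {m: percent[m] / 100.0 for m in _METRIC_ORDER}
        return cls(aggregation=aggregation, **vals)

    def to_json(self) -> str:
        d = {m: getattr(self, m) for m in _METRIC_ORDER}
        d["aggregation"] = self.aggregation
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def compute_metrics(counts, aggregation: str = "macro_per_image") -> MetricsReport:
    """Turn one ConfusionCounts (micro) or a per-image list (macro or micro)
    into a :class:`MetricsReport`."""
    if aggregation not in ("micro_global", "macro_per_image"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if isinstance(counts, ConfusionCounts):
        counts = [counts]
    counts = list(counts)
    if not counts:
        raise ValueError("no images to aggregate")
    if aggregation == "micro_global":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        vals = _metrics_from_counts(pooled)
    else:
        per_image = [_metrics_from_counts(c) for c in counts]
        vals = {m: float(np.mean([pi[m] for pi in per_image])) for m in _METRIC_ORDER}
    return MetricsReport(aggregation=aggregation, **vals)


def f1_from_precision_recall(precision: float, recall: float,
                             percent: bool = True, decimals: int = 2) -> float:
    """Harmonic mean of precision and recall, on the given scale.

    With ``percent=True`` the inputs and output are percentages rounded to
    ``decimals`` places — the convention used in comparison tables.
    """
    if precision + recall == 0:
        return 0.0
    f1 = 2.0 * precision * recall / (precision + recall)
    return round(f1, decimals) if percent else f1


def compare_reports(candidate: MetricsReport, baseline: MetricsReport,
                    decimals: int = 2) -> dict[str, float]:
    """Candidate-minus-baseline per metric, in percentage points."""
    if candidate.aggregation != baseline.aggregation:
        raise ValueError(
            f"aggregation mismatch: {candidate.aggregation!r} vs {baseline.aggregation!r}")
    cand = candidate.as_percent(decimals=10)
    base = baseline.as_percent(decimals=10)
    return {m: round(cand[m] - base[m], decimals) for m in _METRIC_ORDER}


def render_comparison(candidate: MetricsReport, baseline: MetricsReport,
                      names: tuple[str, str] = ("candidate", "baseline")) -> str:
    """Aligned plain-text table: the two reports and their signed deltas."""
    delta = compare_reports(candidate, baseline)
    header = ["Method"] + [m.capitalize() + "(%)" for m in _METRIC_ORDER]
    rows = [
        [names[1]] + [f"{baseline.as_percent()[m]:.2f}" for m in _METRIC_ORDER],
        [names[0]] + [f"{candidate.as_percent()[m]:.2f}" for m in _METRIC_ORDER],
        ["delta"] + [f"{delta[m]:+.2f}" for m in _METRIC_ORDER],
    ]
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(r, widths))
             for r in [header] + rows]
    return "\n".join(lines)
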