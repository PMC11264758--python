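"""Dice/BCE losses and the six-metric suite against analytic values and
scalar-loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stcunet.autodiff import Tensor
from stcunet.losses_metrics import (
    ConfusionCounts,
    MetricsReport,
    bce_loss,
    compare_reports,
    compute_metrics,
    confusion_counts,
    dice_coefficient,
    dice_loss,
    f1_from_precision_recall,
    render_comparison,
    total_loss,
)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_dice_loss_perfect_overlap_is_zero():
    p = np.ones((2, 2))
    assert dice_loss(p, p, epsilon=1.0) == pytest.approx(0.0, abs=1e-12)


def test_dice_loss_total_miss_analytic():
    p = np.zeros((2, 2))
    y = np.ones((2, 2))
    assert dice_loss(p, y, epsilon=1.0) == pytest.approx(0.8, abs=1e-12)


def test_dice_loss_matches_scalar_loop(rng):
    p = rng.random((3, 3))
    y = (rng.random((3, 3)) < 0.5).astype(float)
    eps = 1.0
    num, den = 0.0, 0.0
    for i in range(3):
        for j in range(3):
            num += y[i, j] * p[i, j]
            den += y[i, j] + p[i, j]
    expected = 1.0 - (2.0 * num + eps) / (den + eps)
    assert dice_loss(p, y, eps) == pytest.approx(expected, abs=1e-9)


def test_dice_loss_plus_coefficient_is_one(rng):
    p = rng.random((4, 4))
    y = (rng.random((4, 4)) < 0.3).astype(float)
    assert dice_loss(p, y) + dice_coefficient(p, y) == pytest.approx(1.0, abs=1e-12)


def test_bce_half_probability_is_log_two():
    assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(math.log(2), abs=1e-9)


def test_bce_perfect_prediction_bounded_by_clamp():
    p = np.array([1.0, 0.0])
    y = np.array([1.0, 0.0])
    assert bce_loss(p, y) <= -math.log(1 - 1e-7) + 1e-12
    assert bce_loss(p, y, clamp=1e-12) < bce_loss(p, y, clamp=1e-7)


def test_bce_matches_scalar_loop(rng):
    p = np.clip(rng.random((4, 4)), 0.01, 0.99)
    y = (rng.random((4, 4)) < 0.5).astype(float)
    acc = 0.0
    for i in range(4):
        for j in range(4):
            acc += y[i, j] * math.log(p[i, j]) + (1 - y[i, j]) * math.log(1 - p[i, j])
    assert bce_loss(p, y) == pytest.approx(-acc / 16.0, abs=1e-9)


def test_total_loss_is_sum_of_parts(rng):
    p = rng.random((3, 3))
    y = (rng.random((3, 3)) < 0.5).astype(float)
    lv = total_loss(p, y, epsilon=1.0)
    assert lv.total == pytest.approx(lv.dice + lv.bce, abs=1e-12)
    assert lv.dice == pytest.approx(dice_loss(p, y, 1.0), abs=1e-12)
    assert lv.bce == pytest.approx(bce_loss(p, y), abs=1e-12)


def test_total_loss_gradient_matches_finite_differences(rng):
    p0 = np.clip(rng.random((2, 2)), 0.05, 0.95)
    y = np.array([[1.0, 0.0], [0.0, 1.0]])
    pt = Tensor(p0.copy(), requires_grad=True, dtype=np.float64)
    total_loss(pt, y).tensor.backward()
    eps = 1e-7
    for i in range(2):
        for j in range(2):
            pp, pm = p0.copy(), p0.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            num = (total_loss(pp, y).total - total_loss(pm, y).total) / (2 * eps)
            assert pt.grad[i, j] == pytest.approx(num, rel=1e-3)


def test_loss_shape_mismatch_reports_both_shapes():
    with pytest.raises(ValueError, match=r"\(2, 2\).*\(3, 3\)"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# confusion counts
# ---------------------------------------------------------------------------

def test_confusion_perfect_and_inverted():
    y = np.array([[1, 0], [0, 1]])
    perfect = confusion_counts(y, y)
    assert perfect.fp == perfect.fn == 0
    inverted = confusion_counts(1 - y, y)
    assert inverted.tp == inverted.tn == 0


def test_confusion_matches_counting_loop(rng):
    p = (rng.random((5, 5)) < 0.5).astype(int)
    y = (rng.random((5, 5)) < 0.5).astype(int)
    c = confusion_counts(p, y)
    tp = tn = fp = fn = 0
    for i in range(5):
        for j in range(5):
            if p[i, j] and y[i, j]:
                tp += 1
            elif p[i, j]:
                fp += 1
            elif y[i, j]:
                fn += 1
            else:
                tn += 1
    assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
    assert c.total == 25


def test_confusion_rejects_non_binary():
    with pytest.raises(ValueError, match="binary"):
        confusion_counts(np.array([0, 2]), np.array([0, 1]))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_metrics_analytic_example():
    rep = compute_metrics(ConfusionCounts(tp=2, tn=12, fp=1, fn=1),
                          aggregation="micro_global")
    assert rep.iou == pytest.approx(0.5)
    assert rep.dice == pytest.approx(2 / 3)
    assert rep.accuracy == pytest.approx(0.875)
    assert rep.precision == pytest.approx(2 / 3)
    assert rep.recall == pytest.approx(2 / 3)
    assert rep.f1 == pytest.approx(2 / 3)


@given(st.tuples(st.integers(0, 1000), st.integers(0, 1000),
                 st.integers(0, 1000), st.integers(0, 1000)))
@settings(max_examples=1000, deadline=None)
def test_metric_identities_hold_for_any_counts(counts):
    tp, tn, fp, fn = counts
    if tp + tn + fp + fn == 0:
        return
    rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn), "micro_global")
    for m in ("iou", "dice", "accuracy", "precision", "recall", "f1"):
        assert 0.0 <= getattr(rep, m) <= 1.0
    assert rep.dice >= rep.iou - 1e-12
    assert rep.f1 == pytest.approx(rep.dice, abs=1e-12)


def test_full_frame_prediction_has_recall_one(rng):
    y = (rng.random((6, 6)) < 0.4).astype(int)
    rep = compute_metrics(confusion_counts(np.ones_like(y), y), "micro_global")
    assert rep.recall == pytest.approx(1.0)


def test_empty_prediction_empty_target_convention():
    rep = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0), "micro_global")
    assert rep.precision == 1.0 and rep.recall == 1.0 and rep.dice == 1.0
    rep = compute_metrics(ConfusionCounts(tp=0, tn=8, fp=0, fn=2), "micro_global")
    assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0


def test_macro_equals_micro_for_identical_images():
    c = ConfusionCounts(tp=3, tn=10, fp=2, fn=1)
    macro = compute_metrics([c, c, c], "macro_per_image")
    micro = compute_metrics([c, c, c], "micro_global")
    for m in ("iou", "dice", "accuracy", "precision", "recall", "f1"):
        assert getattr(macro, m) == pytest.approx(getattr(micro, m), abs=1e-12)


def test_zero_images_rejected():
    with pytest.raises(ValueError):
        compute_metrics([], "macro_per_image")


# ---------------------------------------------------------------------------
# comparison arithmetic
# ---------------------------------------------------------------------------

def test_f1_from_percent_precision_recall_pairs():
    assert f1_from_precision_recall(97.05, 96.18) == 96.61
    assert f1_from_precision_recall(98.23, 97.70) == 97.96


def test_compare_reports_improvement_deltas():
    baseline = MetricsReport.from_percent(
        iou=95.80, dice=94.92, accuracy=94.27, precision=97.05, recall=96.18,
        f1=96.61)
    candidate = MetricsReport.from_percent(
        iou=97.40, dice=96.94, accuracy=96.54, precision=98.23, recall=97.70,
        f1=97.96)
    delta = compare_reports(candidate, baseline)
    assert delta["iou"] == 1.60
    assert delta["dice"] == 2.02
    assert delta["accuracy"] == 2.27
    assert delta["precision"] == 1.18
    assert delta["recall"] == 1.52
    assert delta["f1"] == 1.35


def test_compare_identical_reports_is_zero_and_antisymmetric():
    a = MetricsReport.from_percent(iou=90.0, dice=91.0, accuracy=92.0,
                                   precision=93.0, recall=94.0, f1=93.5)
    b = MetricsReport.from_percent(iou=88.5, dice=90.0, accuracy=91.0,
                                   precision=92.0, recall=93.0, f1=92.5)
    assert all(v == 0.0 for v in compare_reports(a, a).values())
    ab = compare_reports(a, b)
    ba = compare_reports(b, a)
    assert all(ab[m] == -ba[m] for m in ab)


def test_compare_rejects_aggregation_mismatch():
    a = MetricsReport(0.9, 0.9, 0.9, 0.9, 0.9, 0.9, aggregation="micro_global")
    b = MetricsReport(0.9, 0.9, 0.9, 0.9, 0.9, 0.9, aggregation="macro_per_image")
    with pytest.raises(ValueError, match="aggregation"):
        compare_reports(a, b)


def test_report_json_round_trip_and_table():
    a = MetricsReport(0.974, 0.9694, 0.9654, 0.9823, 0.977, 0.9796)
    back = MetricsReport.from_json(a.to_json())
    assert back == a
    table = render_comparison(a, a)
    assert "Iou(%)" in table and "+0.00" in table
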