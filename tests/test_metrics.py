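"""Metric suites versus hand-computed cases and independent oracles
(scikit-learn for classification/segmentation, explicit PR staircases
for detection)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from seafec.metrics import (
    box_iou,
    classification_metrics,
    detection_map,
    segmentation_metrics,
)

from oracles import classification_counts_ref


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def test_perfect_prediction_is_all_ones():
    rep = classification_metrics([0, 1, 2, 0], [0, 1, 2, 0], 3)
    for k in ("accuracy", "precision", "recall", "specificity", "f1"):
        assert rep[k] == 1.0


def test_binary_hand_computed_confusion():
    """TP=3, FP=1, FN=2, TN=4 for class 1."""
    y_true = [1] * 5 + [0] * 5
    y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
    rep = classification_metrics(y_true, y_pred, 2)
    assert rep["accuracy"] == pytest.approx(0.7)
    assert rep.per_class["precision"][1] == pytest.approx(0.75)
    assert rep.per_class["recall"][1] == pytest.approx(0.6)
    assert rep.per_class["specificity"][1] == pytest.approx(0.8)
    assert rep.per_class["f1"][1] == pytest.approx(2 / 3)


def test_all_one_class_prediction_zero_specificity():
    rep = classification_metrics([0, 1, 0, 1], [1, 1, 1, 1], 2)
    assert rep.per_class["specificity"][1] == 0.0
    assert any("specificity" in f or "precision" in f for f in rep.flags)


def test_absent_class_flagged_not_crashing():
    rep = classification_metrics([0, 0], [0, 0], 3)
    assert rep.metrics["accuracy"] == 1.0
    assert any("class 1" in f for f in rep.flags)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 40), k=st.integers(2, 5))
def test_classification_agrees_with_confusion_count_oracles(seed, n, k):
    rng = np.random.default_rng(seed)
    y_true = rng.integers(0, k, n)
    y_pred = rng.integers(0, k, n)
    rep = classification_metrics(y_true, y_pred, k)
    counts = classification_counts_ref(y_true, y_pred, k)
    prec = [tp / (tp + fp) if tp + fp else 0.0 for tp, fp, fn, tn in counts]
    rec = [tp / (tp + fn) if tp + fn else 0.0 for tp, fp, fn, tn in counts]
    spec = [tn / (tn + fp) if tn + fp else 0.0 for tp, fp, fn, tn in counts]
    assert rep["accuracy"] == pytest.approx(float(np.mean(y_true == y_pred)))
    assert rep["precision"] == pytest.approx(np.mean(prec))
    assert rep["recall"] == pytest.approx(np.mean(rec))
    assert rep["specificity"] == pytest.approx(np.mean(spec))
    # independent library oracle (zero_division matches the flag-as-0 policy)
    assert rep["precision"] == pytest.approx(
        skm.precision_score(y_true, y_pred, labels=range(k), average="macro", zero_division=0)
    )
    assert rep["recall"] == pytest.approx(
        skm.recall_score(y_true, y_pred, labels=range(k), average="macro", zero_division=0)
    )


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def test_identical_masks_reach_unity():
    m = np.random.default_rng(0).integers(0, 3, (4, 8, 8))
    rep = segmentation_metrics(m, m, 3)
    assert rep["miou"] == 1.0
    assert rep.per_class["iou"] == [1.0, 1.0, 1.0]


def test_disjoint_binary_masks_zero_iou():
    t = np.zeros((1, 4, 4), np.int64)
    p = np.ones((1, 4, 4), np.int64)
    rep = segmentation_metrics(t, p, 2)
    assert rep.per_class["iou"] == [0.0, 0.0]


def test_two_by_two_hand_case():
    t = np.array([[0, 0], [1, 1]])
    p = np.array([[0, 1], [1, 1]])
    rep = segmentation_metrics(t, p, 2)
    assert rep.per_class["iou"][0] == pytest.approx(1 / 2)
    assert rep.per_class["iou"][1] == pytest.approx(2 / 3)
    assert rep["miou"] == pytest.approx(7 / 12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_segmentation_matches_sklearn_jaccard(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 3, (2, 6, 6))
    p = rng.integers(0, 3, (2, 6, 6))
    rep = segmentation_metrics(t, p, 3)
    ref = skm.jaccard_score(t.ravel(), p.ravel(), labels=[0, 1, 2],
                            average=None, zero_division=0)
    np.testing.assert_allclose(rep.per_class["iou"], ref, atol=1e-12)


def test_segmentation_rejects_mismatched_shapes():
    with pytest.raises(ValueError):
        segmentation_metrics(np.zeros((2, 2)), np.zeros((3, 3)), 2)
    with pytest.raises(ValueError):
        segmentation_metrics(np.full((2, 2), 5), np.zeros((2, 2)), 3)


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------

def _one_image(gt, pred, scores, labels_gt=None, labels_pred=None):
    n_gt, n_pred = len(gt), len(pred)
    return dict(
        gt_boxes=[np.array(gt, float)],
        gt_labels=[np.array(labels_gt if labels_gt is not None else [0] * n_gt)],
        pred_boxes=[np.array(pred, float)],
        pred_scores=[np.array(scores, float)],
        pred_labels=[np.array(labels_pred if labels_pred is not None else [0] * n_pred)],
    )


def test_box_iou_basic():
    a = np.array([[0, 0, 2, 2]])
    b = np.array([[1, 1, 3, 3], [0, 0, 2, 2], [4, 4, 5, 5]])
    np.testing.assert_allclose(box_iou(a, b)[0], [1 / 7, 1.0, 0.0])


def test_exact_predictions_reach_unity_regardless_of_scores():
    gt = [[0, 0, 4, 4], [10, 10, 20, 18]]
    rep = detection_map(**_one_image(gt, gt, [0.3, 0.9]))
    assert rep["map50"] == 1.0
    assert rep["map50_95"] == 1.0


def test_no_predictions_zero_ap():
    rep = detection_map(**_one_image([[0, 0, 4, 4]], np.zeros((0, 4)), []))
    assert rep["map50"] == 0.0 and rep["map50_95"] == 0.0


def test_ap_staircase_hand_case():
    """Two truths, three predictions; the top-scored prediction misses and
    the next two hit.  Ranked PR points: (0.5, 1/2), (1, 2/3); all-point
    interpolation gives AP = 2/3."""
    gt = [[0, 0, 10, 10], [20, 20, 30, 30]]
    preds = [[50, 50, 60, 60], [0, 0, 10, 11], [20, 20, 30, 29]]
    rep = detection_map(**_one_image(gt, preds, [0.9, 0.8, 0.7]),
                        iou_thresholds=np.array([0.5]))
    assert rep["map50"] == pytest.approx(2 / 3)


def test_equal_scores_keep_input_order():
    gt = [[0, 0, 10, 10]]
    preds = [[0, 0, 10, 10], [40, 40, 50, 50]]
    r1 = detection_map(**_one_image(gt, preds, [0.5, 0.5]),
                       iou_thresholds=np.array([0.5]))
    # hit listed first at the tied score: precision at rank 1 is 1 -> AP 1
    assert r1["map50"] == pytest.approx(1.0)
    r2 = detection_map(**_one_image(gt, preds[::-1], [0.5, 0.5]),
                       iou_thresholds=np.array([0.5]))
    # miss first: the hit arrives at rank 2 with precision 1/2
    assert r2["map50"] == pytest.approx(0.5)


def test_one_match_per_truth_box():
    gt = [[0, 0, 10, 10]]
    preds = [[0, 0, 10, 10], [0, 0, 10, 10]]  # duplicate detection
    rep = detection_map(**_one_image(gt, preds, [0.9, 0.8]),
                        iou_thresholds=np.array([0.5]))
    # second duplicate is a false positive; AP stays 1 (truth found at rank 1)
    assert rep["map50"] == pytest.approx(1.0)


def test_class_without_ground_truth_excluded_and_flagged():
    rep = detection_map(**_one_image([[0, 0, 4, 4]], [[0, 0, 4, 4], [5, 5, 8, 8]],
                                     [0.9, 0.8], labels_gt=[0], labels_pred=[0, 1]))
    assert rep["map50"] == 1.0
    assert any("class 1" in f for f in rep.flags)


def test_scores_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        detection_map(**_one_image([[0, 0, 4, 4]], [[0, 0, 4, 4]], [1.5]))
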