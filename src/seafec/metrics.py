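"""Metric suites for the three task families.

* classification — accuracy plus macro-averaged one-vs-rest precision,
  recall, specificity and F1 over the confusion matrix;
* segmentation — per-class IoU pooled over all pixels of all images,
  unweighted mean IoU, macro pixel precision/recall;
* detection — COCO-style mean average precision: greedy score-ordered
  matching (one match per ground-truth box), all-point interpolated
  precision-recall area per class, averaged at IoU 0.5 (mAP@50) and over
  thresholds 0.50:0.05:0.95 (mAP@50-95).

All rates are reported in [0, 1].  Undefined rates (zero denominators)
are reported as 0 and listed in ``MetricsReport.flags`` rather than
omitted, so macro averages stay well defined on degenerate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "segmentation_metrics",
    "detection_map",
    "box_iou",
]


@dataclass
class MetricsReport:
    task: str
    metrics: dict[str, float]
    per_class: dict[str, list[float]] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "metrics": self.metrics,
            "per_class": self.per_class,
            "support": self.support,
            "flags": self.flags,
        }


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(f"{what}: undefined (zero denominator), reported as 0")
        return 0.0
    return num / den


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def classification_metrics(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Accuracy and macro one-vs-rest precision/recall/specificity/F1."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    total = int(cm.sum())
    flags: list[str] = []
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    prec, rec, spec, f1 = [], [], [], []
    for c in range(n_classes):
        if tp[c] + fp[c] + fn[c] == 0:
            flags.append(f"class {c}: absent from truth and prediction")
        p = _safe_div(tp[c], tp[c] + fp[c], flags, f"precision[{c}]")
        r = _safe_div(tp[c], tp[c] + fn[c], flags, f"recall[{c}]")
        s = _safe_div(tn[c], tn[c] + fp[c], flags, f"specificity[{c}]")
        f = _safe_div(2 * p * r, p + r, flags, f"f1[{c}]")
        prec.append(p), rec.append(r), spec.append(s), f1.append(f)
    metrics = {
        "accuracy": _safe_div(float(tp.sum()), total, flags, "accuracy"),
        "precision": float(np.mean(prec)),
        "recall": float(np.mean(rec)),
        "specificity": float(np.mean(spec)),
        "f1": float(np.mean(f1)),
    }
    return MetricsReport(
        task="cls",
        metrics=metrics,
        per_class={"precision": prec, "recall": rec, "specificity": spec, "f1": f1},
        support={str(c): int(cm[c].sum()) for c in range(n_classes)},
        flags=flags,
    )


def segmentation_metrics(true_masks, pred_masks, n_classes: int) -> MetricsReport:
    """Pooled per-class IoU, unweighted mIoU, macro pixel precision/recall."""
    t = np.asarray(true_masks)
    p = np.asarray(pred_masks)
    if t.shape != p.shape:
        raise ValueError("mask shapes must match")
    cm = confusion_matrix(t, p, n_classes)
    flags: list[str] = []
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    iou, prec, rec = [], [], []
    for c in range(n_classes):
        iou.append(_safe_div(tp[c], tp[c] + fp[c] + fn[c], flags, f"iou[{c}]"))
        prec.append(_safe_div(tp[c], tp[c] + fp[c], flags, f"precision[{c}]"))
        rec.append(_safe_div(tp[c], tp[c] + fn[c], flags, f"recall[{c}]"))
    metrics = {
        "miou": float(np.mean(iou)),
        "mean_precision": float(np.mean(prec)),
        "mean_recall": float(np.mean(rec)),
    }
    return MetricsReport(
        task="seg",
        metrics=metrics,
        per_class={"iou": iou, "precision": prec, "recall": rec},
        support={str(c): int(cm[c].sum()) for c in range(n_classes)},
        flags=flags,
    )


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N, 4) and (M, 4) half-open boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _average_precision(tp_flags: np.ndarray, n_gt: int) -> float:
    """All-point interpolated PR area for one score-sorted TP/FP sequence."""
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    changes = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[changes + 1] - mrec[changes]) * mpre[changes + 1]))


def detection_map(
    gt_boxes: list[np.ndarray],
    gt_labels: list[np.ndarray],
    pred_boxes: list[np.ndarray],
    pred_scores: list[np.ndarray],
    pred_labels: list[np.ndarray],
    iou_thresholds: np.ndarray | None = None,
) -> MetricsReport:
    """Mean average precision over images, classes and IoU thresholds.

    Predictions are processed in decreasing score order (equal scores
    keep input order); each ground-truth box can match at most one
    prediction per threshold, greedily assigned to the highest-IoU
    unmatched truth.  Classes with no ground truth are excluded from the
    mean and flagged.
    """
    if iou_thresholds is None:
        iou_thresholds = np.arange(0.50, 0.96, 0.05)
    n_img = len(gt_boxes)
    if not (len(gt_labels) == len(pred_boxes) == len(pred_scores) == len(pred_labels) == n_img):
        raise ValueError("per-image lists must have equal length")
    flags: list[str] = []
    for i in range(n_img):
        s = np.asarray(pred_scores[i], dtype=np.float64)
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        for bx in (gt_boxes[i], pred_boxes[i]):
            b = np.asarray(bx, dtype=np.float64).reshape(-1, 4)
            if b.size and ((b[:, 2] <= b[:, 0]).any() or (b[:, 3] <= b[:, 1]).any()):
                raise ValueError("boxes must satisfy x_min < x_max and y_min < y_max")
    classes = sorted(
        {int(c) for lab in gt_labels for c in np.asarray(lab, dtype=np.int64).ravel()}
        | {int(c) for lab in pred_labels for c in np.asarray(lab, dtype=np.int64).ravel()}
    )
    ap_table: dict[int, list[float]] = {}
    n_gt_total = 0
    for cls in classes:
        cls_gt = [
            np.asarray(gt_boxes[i], dtype=np.float64).reshape(-1, 4)[
                np.asarray(gt_labels[i], dtype=np.int64).ravel() == cls
            ]
            for i in range(n_img)
        ]
        n_gt = sum(len(g) for g in cls_gt)
        n_gt_total += n_gt
        if n_gt == 0:
            flags.append(f"class {cls}: predictions but no ground truth; excluded from mean")
            continue
        dets = []  # (score, order, image, box)
        for i in range(n_img):
            lab = np.asarray(pred_labels[i], dtype=np.int64).ravel()
            box = np.asarray(pred_boxes[i], dtype=np.float64).reshape(-1, 4)
            sco = np.asarray(pred_scores[i], dtype=np.float64).ravel()
            for j in np.where(lab == cls)[0]:
                dets.append((sco[j], len(dets), i, box[j]))
        order = sorted(range(len(dets)), key=lambda k: (-dets[k][0], dets[k][1]))
        aps = []
        for thr in iou_thresholds:
            matched = [np.zeros(len(g), dtype=bool) for g in cls_gt]
            tp_flags = np.zeros(len(dets), dtype=bool)
            for rank, k in enumerate(order):
                _, _, img, box = dets[k]
                gts = cls_gt[img]
                if len(gts) == 0:
                    continue
                ious = box_iou(box, gts)[0]
                ious = np.where(matched[img], -1.0, ious)
                best = int(np.argmax(ious))
                if ious[best] >= thr:
                    matched[img][best] = True
                    tp_flags[rank] = True
            aps.append(_average_precision(tp_flags, n_gt) if len(dets) else 0.0)
        ap_table[cls] = aps
    if not ap_table:
        metrics = {"map50": 0.0, "map50_95": 0.0}
        flags.append("no ground-truth boxes; mAP reported as 0")
    else:
        arr = np.array([ap_table[c] for c in ap_table])  # (classes, thresholds)
        metrics = {
            "map50": float(arr[:, 0].mean()),
            "map50_95": float(arr.mean()),
        }
    per_class = {f"ap@{thr:.2f}": [ap_table[c][k] for c in ap_table]
                 for k, thr in enumerate(iou_thresholds)} if ap_table else {}
    return MetricsReport(
        task="det",
        metrics=metrics,
        per_class=per_class,
        support={"gt_boxes": n_gt_total},
        flags=flags,
    )
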