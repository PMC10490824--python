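"""Detection metrics: greedy matching, precision/recall, per-class AP, mAP@0.5.

Matching is greedy by descending confidence within each image: a detection is
a true positive if it has IoU >= threshold with an unmatched same-class
ground-truth box (each gt is consumed at most once).  AP is the area under
the monotone-envelope (all-points interpolated) precision-recall curve, and
mAP averages over the classes present in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Detection


@dataclass
class MatchResult:
    """Per-detection TP/FP flags plus gt bookkeeping, accumulated over images."""

    tp: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    confidences: np.ndarray = field(default_factory=lambda: np.zeros(0))
    det_classes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    n_gt_per_class: dict = field(default_factory=dict)

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return int(sum(self.n_gt_per_class.values()) - self.n_tp)


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, m) IoU matrix of corner-format boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0, None,
    )
    ih = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0, None,
    )
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(area_a[:, None] + area_b[None, :] - inter, 1e-12)


def match_detections(dets: list[Detection], gts, iou_thr: float = 0.5) -> MatchResult:
    """Match one image's detections to its ground truth.

    ``gts``: sequence of (class_id, x1, y1, x2, y2).  Detections are put in a
    canonical order (descending score, ties broken by box coordinates then
    class) so the result is invariant to the input ordering; the returned
    arrays follow that canonical order.
    """
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
    dets = sorted(dets, key=lambda d: (-d.score, d.box, d.class_id))
    tp = np.zeros(len(dets), dtype=bool)
    used = np.zeros(len(gts), dtype=bool)
    if len(dets) and len(gts):
        iou = box_iou_xyxy([d.box for d in dets], gts[:, 1:5])
        for di, d in enumerate(dets):
            same = (gts[:, 0] == d.class_id) & ~used
            if not same.any():
                continue
            cand = np.nonzero(same)[0]
            best = cand[iou[di, cand].argmax()]
            if iou[di, best] >= iou_thr:
                tp[di] = True
                used[best] = True
    counts: dict[int, int] = {}
    for c in gts[:, 0].astype(int):
        counts[c] = counts.get(c, 0) + 1
    return MatchResult(
        tp=tp,
        confidences=np.asarray([d.score for d in dets], dtype=np.float64),
        det_classes=np.asarray([d.class_id for d in dets], dtype=int),
        n_gt_per_class=counts,
    )


def merge_matches(results: list[MatchResult]) -> MatchResult:
    counts: dict[int, int] = {}
    for r in results:
        for c, n in r.n_gt_per_class.items():
            counts[c] = counts.get(c, 0) + n
    return MatchResult(
        tp=np.concatenate([r.tp for r in results]) if results else np.zeros(0, bool),
        confidences=np.concatenate([r.confidences for r in results])
        if results
        else np.zeros(0),
        det_classes=np.concatenate([r.det_classes for r in results])
        if results
        else np.zeros(0, int),
        n_gt_per_class=counts,
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Aggregate precision/recall; precision defaults to 1.0 with no
    detections (documented convention)."""
    tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    ap: float


def average_precision(tp: np.ndarray, conf: np.ndarray, n_gt: int) -> PRCurve:
    """All-points interpolated AP from per-detection flags and confidences."""
    if n_gt == 0 or len(tp) == 0:
        return PRCurve(np.zeros(1), np.ones(1), 0.0)
    order = np.argsort(-conf, kind="stable")
    tp_sorted = tp[order].astype(np.float64)
    cum_tp = np.cumsum(tp_sorted)
    cum_fp = np.cumsum(1.0 - tp_sorted)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # monotone envelope with boundary points
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = float(np.sum((r[1:] - r[:-1]) * p[1:]))
    return PRCurve(recall=r, precision=p, ap=ap)


def evaluate_matches(merged: MatchResult) -> dict:
    """Per-class AP and mAP@0.5 from accumulated match results.

    Classes absent from the ground truth are excluded from the mean.
    """
    per_class: dict[int, PRCurve] = {}
    for c, n_gt in sorted(merged.n_gt_per_class.items()):
        mask = merged.det_classes == c
        per_class[c] = average_precision(
            merged.tp[mask], merged.confidences[mask], n_gt
        )
    aps = [curve.ap for curve in per_class.values()]
    precision, recall = precision_recall(merged)
    return {
        "per_class": per_class,
        "map50": float(np.mean(aps)) if aps else 0.0,
        "precision": precision,
        "recall": recall,
    }


def map50(per_class_ap: dict) -> float:
    vals = [c.ap if isinstance(c, PRCurve) else float(c) for c in per_class_ap.values()]
    return float(np.mean(vals)) if vals else 0.0
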