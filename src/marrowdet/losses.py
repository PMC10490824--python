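"""Training objective: focal classification + CIoU localization + BCE
objectness, combined as Loss = w1*box_loss + w2*cls_loss + w3*obj_loss.

Focal loss (one-vs-all, sigmoid outputs):

    cls_loss = -alpha_t * (1 - p_t)^gamma * log(p_t),
    p_t = p if y=1 else 1-p,   alpha_t = alpha if y=1 else 1-alpha.

CIoU loss for a predicted box b and ground truth b_gt:

    L = 1 - IoU + rho^2(b, b_gt) / c^2 + alpha_v * v,
    v = (4 / pi^2) (arctan(w_gt/h_gt) - arctan(w/h))^2,
    alpha_v = v / ((1 - IoU) + v)      (treated as a constant in gradients),

where rho is the center distance and c the diagonal of the smallest
enclosing box.

Scalar/NumPy forms are the public operations; Tensor forms (same math on
autograd tensors) drive training and are cross-checked against the NumPy
forms in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .model import ModelConfig

_P_CLAMP = 1e-7


@dataclass
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class LossWeights:
    """Weights of the composite loss; YOLO-convention defaults (box/cls/obj)."""

    w_box: float = 0.05
    w_cls: float = 0.3
    w_obj: float = 0.7


@dataclass
class LossBreakdown:
    box_loss: float
    obj_loss: float
    cls_loss: float
    weights: LossWeights = field(default_factory=LossWeights)

    @property
    def total(self) -> float:
        return total_loss(self)


def total_loss(components: LossBreakdown) -> float:
    w = components.weights
    if min(w.w_box, w.w_cls, w.w_obj) < 0:
        raise ValueError("loss weights must be non-negative")
    return (
        w.w_box * components.box_loss
        + w.w_cls * components.cls_loss
        + w.w_obj * components.obj_loss
    )


# ------------------------------------------------------------- scalar / NumPy
def focal_loss(p, y, params: FocalParams = FocalParams()):
    """Focal loss on probabilities p with binary targets y (broadcastable)."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, _P_CLAMP, 1 - _P_CLAMP)
    p_t = np.where(y == 1, p, 1 - p)
    a_t = np.where(y == 1, params.alpha, 1 - params.alpha)
    out = -a_t * (1 - p_t) ** params.gamma * np.log(p_t)
    return float(out) if out.ndim == 0 else out


def bce_obj_loss(pred_obj, target_obj):
    """Binary cross-entropy on (soft) objectness targets."""
    p = np.clip(np.asarray(pred_obj, dtype=np.float64), _P_CLAMP, 1 - _P_CLAMP)
    t = np.asarray(target_obj, dtype=np.float64)
    out = -(t * np.log(p) + (1 - t) * np.log(1 - p))
    return float(out) if out.ndim == 0 else out


def _ciou_terms(pred: np.ndarray, gt: np.ndarray):
    px1, py1, px2, py2 = pred[..., 0], pred[..., 1], pred[..., 2], pred[..., 3]
    gx1, gy1, gx2, gy2 = gt[..., 0], gt[..., 1], gt[..., 2], gt[..., 3]
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1
    inter = np.clip(np.minimum(px2, gx2) - np.maximum(px1, gx1), 0, None) * np.clip(
        np.minimum(py2, gy2) - np.maximum(py1, gy1), 0, None
    )
    union = pw * ph + gw * gh - inter
    iou = inter / np.maximum(union, 1e-12)
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) / 4
    cw = np.maximum(px2, gx2) - np.minimum(px1, gx1)
    ch = np.maximum(py2, gy2) - np.minimum(py1, gy1)
    c2 = np.maximum(cw**2 + ch**2, 1e-12)
    v = (4 / np.pi**2) * (np.arctan(gw / gh) - np.arctan(pw / ph)) ** 2
    alpha_v = v / np.maximum((1 - iou) + v, 1e-12)
    return iou, rho2 / c2, alpha_v * v


def ciou(pred, gt):
    """CIoU similarity (IoU minus distance and aspect penalties), NumPy."""
    iou, dist, aspect = _ciou_terms(np.asarray(pred, float), np.asarray(gt, float))
    out = iou - dist - aspect
    return float(out) if out.ndim == 0 else out


def ciou_loss(pred, gt):
    """CIoU loss = 1 - CIoU, for corner-format boxes (x1, y1, x2, y2)."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if ((pred[..., 2] - pred[..., 0]) <= 0).any() or ((pred[..., 3] - pred[..., 1]) <= 0).any():
        raise ValueError("predicted box has non-positive size")
    if ((gt[..., 2] - gt[..., 0]) <= 0).any() or ((gt[..., 3] - gt[..., 1]) <= 0).any():
        raise ValueError("ground-truth box has non-positive size")
    out = 1.0 - ciou(pred, gt)
    return float(out) if np.ndim(out) == 0 else out


# --------------------------------------------------------------- Tensor forms
def ciou_tensor(pred_xywh: Tensor, gt_xywh: np.ndarray) -> Tensor:
    """CIoU similarity for center-format (cx, cy, w, h) boxes; autograd.

    ``alpha_v`` is evaluated outside the gradient (standard CIoU practice).
    """
    gt = np.asarray(gt_xywh, dtype=np.float32)
    pcx, pcy = pred_xywh[:, 0], pred_xywh[:, 1]
    pw = ag.clamp(pred_xywh[:, 2], 1e-6, None)
    ph = ag.clamp(pred_xywh[:, 3], 1e-6, None)
    gcx, gcy, gw, gh = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    px1, px2 = pcx - pw * 0.5, pcx + pw * 0.5
    py1, py2 = pcy - ph * 0.5, pcy + ph * 0.5
    gx1, gx2 = gcx - gw / 2, gcx + gw / 2
    gy1, gy2 = gcy - gh / 2, gcy + gh / 2
    iw = ag.clamp(ag.minimum(px2, Tensor(gx2)) - ag.maximum(px1, Tensor(gx1)), 0.0, None)
    ih = ag.clamp(ag.minimum(py2, Tensor(gy2)) - ag.maximum(py1, Tensor(gy1)), 0.0, None)
    inter = iw * ih
    union = pw * ph + Tensor(gw * gh) - inter
    iou = inter / ag.clamp(union, 1e-9, None)
    rho2 = ((pcx - gcx) ** 2.0 + (pcy - gcy) ** 2.0)
    cw = ag.maximum(px2, Tensor(gx2)) - ag.minimum(px1, Tensor(gx1))
    chh = ag.maximum(py2, Tensor(gy2)) - ag.minimum(py1, Tensor(gy1))
    c2 = ag.clamp(cw * cw + chh * chh, 1e-9, None)
    v = (ag.atan(Tensor(gw / gh)) - ag.atan(pw / ph)) ** 2.0 * (4.0 / np.pi**2)
    alpha_v = v.data / np.maximum((1.0 - iou.data) + v.data, 1e-9)  # no grad
    return iou - rho2 / c2 - v * Tensor(alpha_v)


def focal_tensor(logits: Tensor, targets: np.ndarray,
                 params: FocalParams) -> Tensor:
    """Mean focal loss from raw logits (autograd)."""
    t = np.asarray(targets, dtype=np.float32)
    p = ag.clamp(ag.sigmoid(logits), _P_CLAMP, 1 - _P_CLAMP)
    p_t = p * t + (1.0 - p) * (1.0 - t)
    a_t = params.alpha * t + (1.0 - params.alpha) * (1.0 - t)
    loss = (1.0 - p_t) ** params.gamma * ag.log(p_t) * Tensor(-a_t)
    return loss.mean()


def bce_logits_tensor(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits: softplus(x) - x*t (stable)."""
    t = np.asarray(targets, dtype=np.float32)
    return (ag.softplus(logits) - logits * Tensor(t)).mean()


# ------------------------------------------------------------ target building
def build_targets(gt_per_image: list, cfg: ModelConfig,
                  anchor_t: float = 4.0) -> list[dict]:
    """Assign ground truth to (level, anchor, cell) positives.

    ``gt_per_image``: per image, an (n, 5) array of (class, cx, cy, w, h) in
    normalized [0, 1] coordinates.  A gt matches an anchor when both wh ratios
    lie within [1/anchor_t, anchor_t]; besides its own cell, each gt also
    marks the two adjacent cells nearest its center (the 0.5-offset
    extension).  When several gts claim the same (image, anchor, cell) slot —
    common for crowded same-sized objects on coarse grids — the slot keeps
    the gt whose wh ratio fits the anchor best (documented tie-break), so
    every positive carries a single consistent regression target.  Returns
    one dict per level with index arrays ``b, a, gj, gi``, target boxes
    ``txywh`` in grid units, classes and matched anchor sizes (grid units).
    """
    size = cfg.input_size
    anchors = cfg.anchors_array()
    out = []
    rows = []
    for b, g in enumerate(gt_per_image):
        g = np.asarray(g, dtype=np.float32).reshape(-1, 5)
        ok = (g[:, 3] > 0) & (g[:, 4] > 0)
        if (~ok).any():
            import warnings

            warnings.warn("skipping ground-truth boxes with non-positive size")
        g = g[ok]
        if len(g):
            rows.append(
                np.column_stack([np.full(len(g), b, dtype=np.float32), g])
            )
    allg = (
        np.concatenate(rows, axis=0)
        if rows
        else np.zeros((0, 6), dtype=np.float32)
    )  # (b, cls, cx, cy, w, h) normalized
    for level, stride in enumerate(cfg.strides):
        grid = size // stride
        anch = anchors[level] / stride  # grid units
        g = allg.copy()
        g[:, 2:6] *= size / stride  # to grid units
        if len(g):
            ratio = g[:, None, 4:6] / anch[None]  # (n, 3, 2)
            fit = np.maximum(ratio, 1.0 / ratio).max(axis=2)  # (n, 3)
            match = fit < anchor_t
            n_idx, a_idx = np.nonzero(match)
            if len(n_idx):
                m = g[n_idx]
                m_fit = fit[n_idx, a_idx]
                # neighbor-cell extension
                cx, cy = m[:, 2], m[:, 3]
                fx, fy = cx % 1.0, cy % 1.0
                selected = [np.zeros(len(m), dtype=bool) | True]
                selected.append((fx < 0.5) & (cx > 1.0))        # left
                selected.append((fy < 0.5) & (cy > 1.0))        # up
                selected.append((fx >= 0.5) & (cx < grid - 1.0))  # right
                selected.append((fy >= 0.5) & (cy < grid - 1.0))  # down
                shift = np.array(
                    [[0, 0], [-1, 0], [0, -1], [1, 0], [0, 1]], dtype=np.float32
                )
                parts, aparts, fparts = [], [], []
                for sel, sh in zip(selected, shift):
                    if not sel.any():
                        continue
                    sub = m[sel].copy()
                    cell = np.floor(sub[:, 2:4] + sh).astype(int)
                    cell = np.clip(cell, 0, grid - 1)
                    parts.append(
                        np.column_stack([sub[:, 0], sub[:, 1], cell, sub[:, 2:6]])
                    )
                    aparts.append(a_idx[sel])
                    fparts.append(m_fit[sel])
                tab = np.concatenate(parts, axis=0)
                a_all = np.concatenate(aparts, axis=0)
                f_all = np.concatenate(fparts, axis=0)
                # conflict resolution: one target per (image, anchor, cell)
                slot = np.column_stack(
                    [tab[:, 0], a_all, tab[:, 2], tab[:, 3]]
                ).astype(int)
                order = np.lexsort((f_all, slot[:, 3], slot[:, 2], slot[:, 1],
                                    slot[:, 0]))
                slot_sorted = slot[order]
                first = np.ones(len(order), dtype=bool)
                first[1:] = (slot_sorted[1:] != slot_sorted[:-1]).any(axis=1)
                keep = order[first]
                tab, a_all = tab[keep], a_all[keep]
                b_arr = tab[:, 0].astype(int)
                cls_arr = tab[:, 1].astype(int)
                gi_arr = tab[:, 2].astype(int)
                gj_arr = tab[:, 3].astype(int)
                txywh = tab[:, 4:8].astype(np.float32)
                out.append(
                    dict(
                        b=b_arr, a=a_all, gj=gj_arr, gi=gi_arr, txywh=txywh,
                        cls=cls_arr, anchors=anch[a_all], grid=grid,
                    )
                )
                continue
        out.append(
            dict(
                b=np.zeros(0, int), a=np.zeros(0, int), gj=np.zeros(0, int),
                gi=np.zeros(0, int), txywh=np.zeros((0, 4), np.float32),
                cls=np.zeros(0, int), anchors=np.zeros((0, 2), np.float32),
                grid=grid,
            )
        )
    return out


class ComputeLoss:
    """Composite detection loss over the three prediction levels."""

    # per-level objectness balance (fine -> coarse), YOLO convention
    LEVEL_BALANCE = (4.0, 1.0, 0.4)

    def __init__(self, cfg: ModelConfig, weights: LossWeights = None,
                 focal: FocalParams = None, anchor_t: float = 4.0,
                 soft_obj: bool = True, obj_gain: float = 1.0):
        self.cfg = cfg
        self.weights = weights or LossWeights()
        self.focal = focal or FocalParams()
        self.anchor_t = anchor_t
        self.soft_obj = soft_obj  # IoU-aware objectness label vs hard 1
        # obj_gain blends the soft label toward 1: t = 1 - g + g*CIoU.
        # g=1 is the pure IoU-aware label; smaller g keeps localization-aware
        # ranking while bounding the label entropy.
        self.obj_gain = obj_gain

    def __call__(self, preds: list[Tensor], gt_per_image: list):
        cfg = self.cfg
        targets = build_targets(gt_per_image, cfg, anchor_t=self.anchor_t)
        box_loss = Tensor(0.0)
        cls_loss = Tensor(0.0)
        obj_loss = Tensor(0.0)
        n_pos_total = 0
        for level, (pred, tgt) in enumerate(zip(preds, targets)):
            n, _, h, w_ = pred.shape
            no = cfg.num_outputs
            p = pred.reshape(n, 3, no, h, w_).transpose(0, 1, 3, 4, 2)  # (N,3,H,W,no)
            obj_target = np.zeros((n, 3, h, w_), dtype=np.float32)
            npos = len(tgt["b"])
            if npos:
                n_pos_total += npos
                idx = (tgt["b"], tgt["a"], tgt["gj"], tgt["gi"])
                ps = p[idx]  # (npos, no)
                pxy = ag.sigmoid(ps[:, 0:2]) * 2.0 - 0.5 + Tensor(
                    np.column_stack([tgt["gi"], tgt["gj"]]).astype(np.float32)
                )
                pwh = (ag.sigmoid(ps[:, 2:4]) * 2.0) ** 2.0 * Tensor(tgt["anchors"])
                pbox = ag.cat([pxy, pwh], axis=1)
                iou = ciou_tensor(pbox, tgt["txywh"])
                box_loss = box_loss + (1.0 - iou).mean()
                if self.soft_obj:
                    g = self.obj_gain
                    obj_target[idx] = 1.0 - g + g * np.clip(iou.data, 0.0, 1.0)
                else:
                    obj_target[idx] = 1.0
                if cfg.num_classes > 1:
                    t_cls = np.zeros((npos, cfg.num_classes), dtype=np.float32)
                    t_cls[np.arange(npos), tgt["cls"]] = 1.0
                    cls_loss = cls_loss + focal_tensor(ps[:, 5:], t_cls, self.focal)
            obj_loss = obj_loss + bce_logits_tensor(
                p[:, :, :, :, 4], obj_target
            ) * self.LEVEL_BALANCE[level]
        w = self.weights
        total = w.w_box * box_loss + w.w_cls * cls_loss + w.w_obj * obj_loss
        breakdown = LossBreakdown(
            box_loss=float(box_loss.data), obj_loss=float(obj_loss.data),
            cls_loss=float(cls_loss.data), weights=w,
        )
        return total, breakdown
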