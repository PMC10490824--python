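"""Closed-form and oracle checks of the composite detection loss."""

import numpy as np
import pytest

from marrowdet.autograd import Tensor
from marrowdet.losses import (
    ComputeLoss,
    FocalParams,
    LossBreakdown,
    LossWeights,
    bce_obj_loss,
    build_targets,
    ciou,
    ciou_loss,
    ciou_tensor,
    focal_loss,
    focal_tensor,
    total_loss,
)
from marrowdet.model import ModelConfig


# ---------------------------------------------------------------- focal loss
def test_focal_gamma_zero_is_alpha_scaled_bce():
    for p in (0.1, 0.5, 0.9):
        for y in (0, 1):
            focal = focal_loss(p, y, FocalParams(alpha=0.5, gamma=0.0))
            bce = bce_obj_loss(p, y)
            assert focal == pytest.approx(0.5 * bce, rel=1e-9)


def test_focal_closed_form_values():
    # y=1, p=0.5, alpha=0.25, gamma=2 -> 0.25 * 0.25 * ln 2
    assert focal_loss(0.5, 1, FocalParams(0.25, 2.0)) == pytest.approx(
        0.25 * 0.25 * np.log(2), rel=1e-6
    )
    assert focal_loss(1 - 1e-9, 1, FocalParams(0.25, 2.0)) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        focal_loss(1.2, 1)


def test_focal_bounded_by_alpha_scaled_bce_and_gamma_monotone():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.01, 0.99, 50)
    y = rng.integers(0, 2, 50)
    alpha = 0.25
    a_t = np.where(y == 1, alpha, 1 - alpha)
    assert (focal_loss(p, y, FocalParams(alpha, 2.0)) <= a_t * bce_obj_loss(p, y) + 1e-12).all()
    # well-classified samples: higher gamma never increases the loss
    p_good, y_good = 0.8, 1
    losses = [focal_loss(p_good, y_good, FocalParams(alpha, g)) for g in (0, 0.5, 1, 2, 5)]
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_focal_tensor_matches_numpy_form():
    rng = np.random.default_rng(1)
    logits = rng.normal(0, 2, (6, 4)).astype(np.float32)
    targets = (rng.random((6, 4)) < 0.3).astype(np.float32)
    params = FocalParams(0.25, 2.0)
    t_val = float(focal_tensor(Tensor(logits), targets, params).data)
    np_val = focal_loss(1 / (1 + np.exp(-logits)), targets, params).mean()
    assert t_val == pytest.approx(np_val, rel=1e-4)


# ------------------------------------------------------------------ BCE / sum
def test_bce_values_and_symmetry():
    assert bce_obj_loss(1 - 1e-9, 1.0) == pytest.approx(0.0, abs=1e-6)
    assert bce_obj_loss(0.5, 1.0) == pytest.approx(np.log(2), rel=1e-9)
    assert bce_obj_loss(0.3, 0.8) == pytest.approx(bce_obj_loss(0.7, 0.2), rel=1e-9)


def test_total_loss_weighted_sum_identity():
    lb = LossBreakdown(box_loss=2, obj_loss=5, cls_loss=3,
                       weights=LossWeights(0.05, 0.3, 0.7))
    assert total_loss(lb) == pytest.approx(0.05 * 2 + 0.3 * 3 + 0.7 * 5)  # = 4.5
    assert total_loss(LossBreakdown(0, 0, 0)) == 0.0
    assert total_loss(
        LossBreakdown(box_loss=2, obj_loss=5, cls_loss=3, weights=LossWeights(1, 0, 0))
    ) == pytest.approx(2.0)


# ----------------------------------------------------------------------- CIoU
def test_ciou_loss_zero_on_identical_boxes():
    assert ciou_loss((0, 0, 4, 6), (0, 0, 4, 6)) == pytest.approx(0.0, abs=1e-12)


def test_ciou_reduces_to_iou_for_concentric_same_aspect():
    # same centers, same aspect ratio, different scale: loss = 1 - IoU
    pred = (-2, -1, 2, 1)   # 4x2 at origin
    gt = (-4, -2, 4, 2)     # 8x4 at origin
    iou = (4 * 2) / (8 * 4)
    assert ciou_loss(pred, gt) == pytest.approx(1 - iou, rel=1e-9)


def test_ciou_hand_computed_disjoint_case():
    # pred (0,0,2,2), gt (4,4,6,6): IoU=0, rho^2=32, c^2=72, v=0 (both square)
    assert ciou_loss((0, 0, 2, 2), (4, 4, 6, 6)) == pytest.approx(1 + 32 / 72, rel=1e-9)
    with pytest.raises(ValueError):
        ciou_loss((0, 0, 0, 2), (4, 4, 6, 6))


def test_ciou_positive_for_distinct_boxes():
    assert ciou_loss((0, 0, 2, 3), (0.5, 0, 2.5, 3)) > 0


def test_ciou_tensor_matches_numpy_form():
    rng = np.random.default_rng(2)
    n = 20
    pred_xywh = np.column_stack(
        [rng.uniform(5, 15, (n, 2)), rng.uniform(2, 8, (n, 2))]
    ).astype(np.float32)
    gt_xywh = np.column_stack(
        [rng.uniform(5, 15, (n, 2)), rng.uniform(2, 8, (n, 2))]
    ).astype(np.float32)

    def to_xyxy(b):
        return np.column_stack(
            [b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2,
             b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2]
        )

    t_val = ciou_tensor(Tensor(pred_xywh), gt_xywh).data
    np_val = ciou(to_xyxy(pred_xywh), to_xyxy(gt_xywh))
    assert np.allclose(t_val, np_val, atol=1e-4)


# -------------------------------------------------------------- target builder
def _toy_cfg():
    return ModelConfig(
        num_classes=3, input_size=64, width_scale=0.125,
        anchors=(((8, 8), (10, 14), (14, 10)),
                 ((16, 16), (20, 28), (28, 20)),
                 ((32, 32), (40, 56), (56, 40))),
    )


def test_gt_equal_to_anchor_at_cell_center_is_positive():
    cfg = _toy_cfg()
    # 8x8 px box centered in a stride-8 cell == anchor 0 of level 0
    gt = [np.array([[0, 0.5 + 1 / 16, 0.5 + 1 / 16, 8 / 64, 8 / 64]])]
    tgt = build_targets(gt, cfg)
    lvl0 = tgt[0]
    assert len(lvl0["b"]) > 0
    assert 0 in lvl0["a"]


def test_oversized_gt_has_no_positives_at_fine_level():
    cfg = _toy_cfg()
    # 10x the largest level-0 anchor: ratio test fails everywhere on level 0
    gt = [np.array([[1, 0.5, 0.5, 140 / 64, 140 / 64]])]
    tgt = build_targets(gt, cfg)
    assert len(tgt[0]["b"]) == 0


def _brute_force_positives(gt_rows, cfg, anchor_t=4.0):
    """Exhaustive enumeration of the documented assignment rule."""
    size = cfg.input_size
    anchors = cfg.anchors_array()
    positives = set()
    for level, stride in enumerate(cfg.strides):
        grid = size // stride
        for b, (cls, cx, cy, w, h) in enumerate(gt_rows):
            gx, gy, gw, gh = (v * size / stride for v in (cx, cy, w, h))
            for a in range(3):
                aw, ah = anchors[level, a] / stride
                r = max(gw / aw, aw / gw, gh / ah, ah / gh)
                if r >= anchor_t:
                    continue
                cells = [(int(gx), int(gy))]
                fx, fy = gx % 1, gy % 1
                if fx < 0.5 and gx > 1:
                    cells.append((int(gx) - 1, int(gy)))
                if fy < 0.5 and gy > 1:
                    cells.append((int(gx), int(gy) - 1))
                if fx >= 0.5 and gx < grid - 1:
                    cells.append((int(gx) + 1, int(gy)))
                if fy >= 0.5 and gy < grid - 1:
                    cells.append((int(gx), int(gy) + 1))
                for gi, gj in cells:
                    positives.add((level, 0, a, min(max(gj, 0), grid - 1),
                                   min(max(gi, 0), grid - 1)))
    return positives


def test_build_targets_matches_exhaustive_enumeration():
    cfg = _toy_cfg()
    gt_rows = [
        (0, 0.31, 0.42, 0.15, 0.13),
        (1, 0.72, 0.18, 0.30, 0.36),
        (2, 0.55, 0.81, 0.58, 0.52),
    ]
    tgt = build_targets([np.array(gt_rows, dtype=np.float32)], cfg)
    got = set()
    for level, t in enumerate(tgt):
        for b, a, gj, gi in zip(t["b"], t["a"], t["gj"], t["gi"]):
            got.add((level, int(b), int(a), int(gj), int(gi)))
    assert got == _brute_force_positives(gt_rows, cfg)


def test_nonpositive_gt_skipped_with_warning():
    cfg = _toy_cfg()
    with pytest.warns(UserWarning):
        tgt = build_targets([np.array([[0, 0.5, 0.5, 0.0, 0.1]])], cfg)
    assert all(len(t["b"]) == 0 for t in tgt)


def test_compute_loss_breakdown_satisfies_weighted_sum(rng, tiny_cfg):
    from marrowdet.model import build_model

    model = build_model(tiny_cfg, seed=0)
    imgs = rng.uniform(0, 1, (2, 3, 192, 192)).astype(np.float32)
    gts = [np.array([[0, 0.5, 0.5, 0.1, 0.1]], np.float32),
           np.array([[1, 0.3, 0.6, 0.08, 0.12]], np.float32)]
    criterion = ComputeLoss(tiny_cfg)
    total, bd = criterion(model(Tensor(imgs)), gts)
    assert float(total.data) == pytest.approx(total_loss(bd), rel=1e-5)
    assert bd.box_loss >= 0 and bd.cls_loss >= 0 and bd.obj_loss >= 0
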