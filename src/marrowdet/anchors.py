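"""Anchor-box optimization: k-means++ under the 1 - IoU distance.

Ground-truth boxes are clustered as (width, height) pairs aligned at a common
origin; the distance between a box x and a center c is D(x) = 1 - IoU(x, c),
seeding probabilities are P(x) = D(x)^2 / sum_i D(x_i)^2 (squared-distance
roulette), and Lloyd updates take the per-cluster arithmetic mean of widths
and heights.  The nine resulting anchors are split by area over the three
detection levels (largest on the coarsest stride).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SizeBox:
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box dims must be positive, got {self}")


@dataclass
class AnchorSet:
    """Nine anchors grouped 3-per-level, level order (stride 32, 16, 8)."""

    levels: tuple  # ((SizeBox,)*3,)*3, coarsest first

    def __post_init__(self):
        if len(self.levels) != 3 or any(len(lvl) != 3 for lvl in self.levels):
            raise ValueError("AnchorSet needs 3 levels x 3 anchors")

    @property
    def strides(self) -> tuple:
        return (32, 16, 8)

    def for_model_config(self) -> tuple:
        """Re-order to model-config convention (stride 8 first), integer px."""
        return tuple(
            tuple((int(round(a.width)), int(round(a.height))) for a in lvl)
            for lvl in reversed(self.levels)
        )


def iou_wh(a, b) -> float:
    """IoU of two origin-aligned boxes given as (w, h) or SizeBox."""
    aw, ah = (a.width, a.height) if isinstance(a, SizeBox) else a
    bw, bh = (b.width, b.height) if isinstance(b, SizeBox) else b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("iou_wh requires positive box dimensions")
    inter = min(aw, bw) * min(ah, bh)
    return inter / (aw * ah + bw * bh - inter)


def _as_array(boxes) -> np.ndarray:
    arr = np.asarray(
        [(b.width, b.height) if isinstance(b, SizeBox) else tuple(b) for b in boxes],
        dtype=np.float64,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("boxes must be (w, h) pairs")
    if (arr <= 0).any():
        raise ValueError("boxes must have positive dimensions")
    return arr


def _iou_matrix(boxes: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n_boxes, n_centers) IoU of origin-aligned size boxes."""
    inter = np.minimum(boxes[:, None, 0], centers[None, :, 0]) * np.minimum(
        boxes[:, None, 1], centers[None, :, 1]
    )
    area_b = boxes.prod(axis=1)[:, None]
    area_c = centers.prod(axis=1)[None, :]
    return inter / (area_b + area_c - inter)


def kmeanspp_seed(boxes, k: int, rng_seed: int | np.random.Generator = 0) -> list[SizeBox]:
    """Draw k distinct initial centers with squared-distance roulette."""
    arr = _as_array(boxes)
    if len(np.unique(arr, axis=0)) < k:
        raise ValueError(f"need at least {k} unique boxes, got {len(np.unique(arr, axis=0))}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    centers = [arr[rng.integers(len(arr))]]
    while len(centers) < k:
        d = 1.0 - _iou_matrix(arr, np.asarray(centers))
        d_min = d.min(axis=1)
        weights = d_min**2
        total = weights.sum()
        if total <= 0:
            raise ValueError("fewer distinct boxes than requested centers")
        centers.append(arr[rng.choice(len(arr), p=weights / total)])
    return [SizeBox(*c) for c in centers]


def _lloyd(arr: np.ndarray, centers: np.ndarray, k: int, max_iter: int) -> np.ndarray:
    assign = np.full(len(arr), -1)
    for _ in range(max_iter):
        d = 1.0 - _iou_matrix(arr, centers)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for i in range(k):
            members = arr[assign == i]
            if len(members):
                centers[i] = members.mean(axis=0)
            else:  # documented policy: re-seed from the farthest box
                centers[i] = arr[d.min(axis=1).argmax()]
    return centers


def cluster_anchors(boxes, k: int = 9, rng_seed: int = 0,
                    max_iter: int = 300, n_init: int = 10) -> list[SizeBox]:
    """IoU k-means: k-means++ seeding, Lloyd iterations with mean updates.

    Boxes are sorted before seeding so the result is invariant to input
    order for a fixed seed.  Iteration stops when assignments are unchanged;
    an emptied cluster is re-seeded from the box farthest from its center.
    ``n_init`` independent seedings are run (all derived from ``rng_seed``)
    and the solution with the smallest total within-cluster distance wins.
    """
    arr = _as_array(boxes)
    if len(arr) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(arr)}")
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    rng = np.random.default_rng(rng_seed)
    best_centers, best_total = None, np.inf
    for _ in range(max(n_init, 1)):
        centers = np.asarray(
            [(c.width, c.height) for c in kmeanspp_seed(arr, k, rng)]
        )
        centers = _lloyd(arr, centers, k, max_iter)
        total = (1.0 - _iou_matrix(arr, centers)).min(axis=1).sum()
        if total < best_total:
            best_total, best_centers = total, centers
    return [SizeBox(*c) for c in best_centers]


def assign_levels(anchors) -> AnchorSet:
    """Split nine anchors by area across the three strides (32, 16, 8).

    Ties in area break by width, then height.
    """
    boxes = [a if isinstance(a, SizeBox) else SizeBox(*a) for a in anchors]
    if len(boxes) != 9:
        raise ValueError(f"expected 9 anchors, got {len(boxes)}")
    ordered = sorted(boxes, key=lambda b: (b.width * b.height, b.width, b.height),
                     reverse=True)
    return AnchorSet(levels=(tuple(ordered[0:3]), tuple(ordered[3:6]), tuple(ordered[6:9])))


def anchors_from_labels(wh_fractions: np.ndarray, img_size: int, k: int = 9,
                        rng_seed: int = 0) -> AnchorSet:
    """Cluster normalized label sizes scaled to network-input pixels."""
    boxes = np.asarray(wh_fractions, dtype=np.float64) * img_size
    return assign_levels(cluster_anchors(boxes, k=k, rng_seed=rng_seed))
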