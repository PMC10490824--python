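"""Confidence filtering and CIoU-based non-maximum suppression.

The suppression statistic is the CIoU *similarity* (IoU minus the center
distance and aspect-ratio penalties): a candidate is removed when its CIoU
with an already-kept higher-scoring box of the same class exceeds the
suppression threshold.  Suppression is class-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import ciou
from .model import Detection


@dataclass
class NMSConfig:
    conf_threshold: float = 0.25
    ciou_threshold: float = 0.45
    max_detections: int = 300

    def __post_init__(self):
        if not np.isfinite(self.conf_threshold) or not np.isfinite(self.ciou_threshold):
            raise ValueError("thresholds must be finite")
        if self.max_detections < 1:
            raise ValueError("max_detections must be >= 1")


def ciou_nms(dets: list[Detection], cfg: NMSConfig = NMSConfig()) -> list[Detection]:
    """Greedy class-wise NMS under the CIoU similarity.

    Returns kept detections sorted by descending score.
    """
    cand = [d for d in dets if d.score >= cfg.conf_threshold]
    if not cand:
        return []
    cand.sort(key=lambda d: -d.score)
    boxes = np.asarray([d.box for d in cand], dtype=np.float64)
    classes = np.asarray([d.class_id for d in cand])
    keep: list[int] = []
    alive = np.ones(len(cand), dtype=bool)
    for i in range(len(cand)):
        if not alive[i]:
            continue
        keep.append(i)
        if len(keep) >= cfg.max_detections:
            break
        rest = np.nonzero(alive[i + 1:])[0] + i + 1
        if len(rest) == 0:
            continue
        same = rest[classes[rest] == classes[i]]
        if len(same) == 0:
            continue
        overlap = ciou(np.broadcast_to(boxes[i], (len(same), 4)), boxes[same])
        alive[same[np.atleast_1d(overlap) > cfg.ciou_threshold]] = False
    return [cand[i] for i in keep]
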