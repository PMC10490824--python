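"""Assembly of the full detector: backbone, neck, head, decode.

The architecture is the YOLOv7 lead-head layout with two switchable
modifications in the backbone: ELAN blocks replaced by CoTLAN
(contextual-transformer final stage) and a CoordAtt block inserted after each
backbone downsampling (MP) stage.  With both toggles off the graph reduces to
the plain CBS+ELAN baseline.

``width_scale`` shrinks every internal channel count (to a multiple of 8,
minimum 8) so that desk-scale models can be trained on a CPU; the default
scale of 1.0 reproduces the published channel plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Identity, Module, set_rng
from .blocks import (
    CBS,
    ELAN,
    MP,
    CoTLAN,
    CoordAtt,
    CoordAttConfig,
    RepC,
    SPPCSP,
)

CHECKPOINT_FORMAT_VERSION = 1

# Anchor priors (input-space pixels) from IoU k-means++ clustering of the
# bone-marrow-cell boxes, grouped per stride; see the anchors module.
DEFAULT_ANCHORS = (
    ((38, 39), (42, 57), (51, 49)),   # stride 8  (80x80 map at 640)
    ((60, 40), (54, 56), (57, 64)),   # stride 16 (40x40 map)
    ((61, 55), (67, 64), (74, 75)),   # stride 32 (20x20 map)
)


@dataclass
class ModelConfig:
    num_classes: int = 15
    input_size: int = 640
    width_scale: float = 1.0
    strides: tuple = (8, 16, 32)
    anchors: tuple = DEFAULT_ANCHORS
    cotlan_enabled: bool = True
    coordatt_enabled: bool = True
    cot_groups: int = 4
    cot_reduction: int = 4
    coordatt_reduction: int = 32
    deploy: bool = False

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        anchors = tuple(tuple(tuple(a) for a in lvl) for lvl in self.anchors)
        if len(anchors) != 3 or any(len(lvl) != 3 for lvl in anchors):
            raise ValueError("anchors must be 3 levels x 3 (w, h) pairs")
        self.anchors = anchors
        self.strides = tuple(self.strides)

    @property
    def num_outputs(self) -> int:
        return 5 + self.num_classes

    def anchors_array(self) -> np.ndarray:
        """(3, 3, 2) float array, level order = stride order (8, 16, 32)."""
        return np.asarray(self.anchors, dtype=np.float32)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class Detection:
    """One decoded prediction: corner-format pixel box, score, class."""

    box: tuple  # (x1, y1, x2, y2), half-open pixel interval
    score: float
    class_id: int

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")


def _width(c: int, scale: float) -> int:
    return max(8, int(round(c * scale / 8)) * 8)


class _ELANW(Module):
    """Neck-flavor aggregation block: six taps (two 1x1 entries + a chain of
    four 3x3 convs at reduced width), concat, 1x1 merge."""

    def __init__(self, c1: int, c_branch: int, c_chain: int, c2: int):
        super().__init__()
        self.cv1 = CBS(c1, c_branch, 1, 1)
        self.cv2 = CBS(c1, c_branch, 1, 1)
        self.chain = [
            CBS(c_branch, c_chain, 3, 1),
            CBS(c_chain, c_chain, 3, 1),
            CBS(c_chain, c_chain, 3, 1),
            CBS(c_chain, c_chain, 3, 1),
        ]
        self.merge = CBS(2 * c_branch + 4 * c_chain, c2, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        y1, y2 = self.cv1(x), self.cv2(x)
        taps = [y2, y1]
        t = y2
        for conv in self.chain:
            t = conv(t)
            taps.insert(0, t)
        return self.merge(ag.cat(taps, axis=1))


class Detector(Module):
    """Full detector producing three raw prediction maps (strides 8/16/32)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        ws = cfg.width_scale
        w = lambda c: _width(c, ws)  # noqa: E731

        def elan(c1, ch, c2):
            if cfg.cotlan_enabled:
                return CoTLAN(c1, ch, c2, cot_groups=cfg.cot_groups,
                              cot_reduction=cfg.cot_reduction)
            return ELAN(c1, ch, c2)

        def coordatt(c):
            if cfg.coordatt_enabled:
                return CoordAtt(CoordAttConfig(c, reduction=cfg.coordatt_reduction))
            return Identity()

        # backbone
        self.stem = [
            CBS(3, w(32), 3, 1),
            CBS(w(32), w(64), 3, 2),
            CBS(w(64), w(64), 3, 1),
            CBS(w(64), w(128), 3, 2),
        ]
        self.elan1 = elan(w(128), w(64), w(256))
        self.mp1 = MP(w(256))
        self.ca1 = coordatt(w(256))
        self.elan2 = elan(w(256), w(128), w(512))
        self.mp2 = MP(w(512))
        self.ca2 = coordatt(w(512))
        self.elan3 = elan(w(512), w(256), w(1024))
        self.mp3 = MP(w(1024))
        self.ca3 = coordatt(w(1024))
        self.elan4 = elan(w(1024), w(256), w(1024))
        # neck
        self.spp = SPPCSP(w(1024), w(512))
        self.lat5 = CBS(w(512), w(256), 1, 1)
        self.lat4 = CBS(w(1024), w(256), 1, 1)
        self.elanw4 = _ELANW(w(512), w(256), w(128), w(256))
        self.lat4b = CBS(w(256), w(128), 1, 1)
        self.lat3 = CBS(w(512), w(128), 1, 1)
        self.elanw3 = _ELANW(w(256), w(128), w(64), w(128))
        self.down3 = MP(w(128), 2 * w(128))
        self.elanw4b = _ELANW(w(256) + 2 * w(128), w(256), w(128), w(256))
        self.down4 = MP(w(256), 2 * w(256))
        self.elanw5b = _ELANW(w(512) + 2 * w(256), w(512), w(256), w(512))
        # head
        no = 3 * cfg.num_outputs
        self.rep3 = RepC(w(128), w(256), deploy=cfg.deploy)
        self.rep4 = RepC(w(256), w(512), deploy=cfg.deploy)
        self.rep5 = RepC(w(512), w(1024), deploy=cfg.deploy)
        self.head3 = Conv2d(w(256), no, 1, bias=True)
        self.head4 = Conv2d(w(512), no, 1, bias=True)
        self.head5 = Conv2d(w(1024), no, 1, bias=True)
        self._init_head_biases()
        self.intermediates: dict[str, tuple] = {}

    def _init_head_biases(self) -> None:
        # Prior-aware bias init: low objectness, near-uniform class logits.
        nc, size = self.cfg.num_classes, self.cfg.input_size
        for head, stride in zip((self.head3, self.head4, self.head5), self.cfg.strides):
            b = head.bias.data.reshape(3, self.cfg.num_outputs)
            b[:, 4] = np.log(8.0 / (size / stride) ** 2)
            b[:, 5:] = np.log(0.6 / (nc - 0.99)) if nc > 1 else 0.0
            head.bias.data = b.reshape(-1)

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {x.shape[2:]}")
        for conv in self.stem:
            x = conv(x)
        x = self.ca1(self.mp1(self.elan1(x)))
        p3 = self.elan2(x)                      # stride 8
        p4 = self.elan3(self.ca2(self.mp2(p3)))  # stride 16
        p5 = self.elan4(self.ca3(self.mp3(p4)))  # stride 32
        spp = self.spp(p5)
        self.intermediates = {"sppcsp": spp.shape}
        f4 = self.elanw4(ag.cat([self.lat4(p4), ag.upsample_nearest2x(self.lat5(spp))], axis=1))
        f3 = self.elanw3(ag.cat([self.lat3(p3), ag.upsample_nearest2x(self.lat4b(f4))], axis=1))
        h4 = self.elanw4b(ag.cat([self.down3(f3), f4], axis=1))
        h5 = self.elanw5b(ag.cat([self.down4(h4), spp], axis=1))
        return [
            self.head3(self.rep3(f3)),
            self.head4(self.rep4(h4)),
            self.head5(self.rep5(h5)),
        ]

    def fuse(self) -> "Detector":
        """Fuse all RepC blocks into deploy form."""
        for rep in (self.rep3, self.rep4, self.rep5):
            if not rep.deploy:
                rep.fuse()
        self.cfg.deploy = True
        return self


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    """Construct a detector with reproducible (seeded) initialization."""
    set_rng(np.random.default_rng(seed))
    return Detector(cfg)


def count_parameters(model: Module) -> int:
    """Total number of learnable scalar parameters."""
    return int(sum(p.size for p in model.parameters()))


def model_forward(model: Detector, images: Tensor) -> list[Tensor]:
    return model(images)


# ------------------------------------------------------------------ decoding
def _level_geometry(cfg: ModelConfig, level: int, h: int, w: int):
    stride = cfg.strides[level]
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float32)
    anchors = cfg.anchors_array()[level]  # (3, 2) pixels
    return stride, gx, gy, anchors

def decode_level(pred: np.ndarray, cfg: ModelConfig, level: int) -> tuple:
    """Decode one raw map (N, 3*no, H, W) -> (boxes_xyxy, scores, class_ids).

    Parametrization (documented contract, also inverted by
    :func:`encode_box`):

    * center  = (2*sigmoid(t_xy) - 0.5 + grid) * stride
    * size    = (2*sigmoid(t_wh))^2 * anchor
    * score   = sigmoid(t_obj) * sigmoid(t_cls)
    """
    n, _, h, w = pred.shape
    no = cfg.num_outputs
    stride, gx, gy, anchors = _level_geometry(cfg, level, h, w)
    p = pred.reshape(n, 3, no, h, w)
    sig = 1.0 / (1.0 + np.exp(-np.clip(p, -60.0, 60.0)))
    cx = (2 * sig[:, :, 0] - 0.5 + gx) * stride
    cy = (2 * sig[:, :, 1] - 0.5 + gy) * stride
    bw = (2 * sig[:, :, 2]) ** 2 * anchors[None, :, 0, None, None]
    bh = (2 * sig[:, :, 3]) ** 2 * anchors[None, :, 1, None, None]
    obj = sig[:, :, 4]
    cls = sig[:, :, 5:]
    scores = obj[:, :, None] * cls  # (N, 3, nc, H, W)
    boxes = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=-1)
    return boxes, scores


def decode_predictions(preds: list, cfg: ModelConfig,
                       conf_threshold: float = 0.001) -> list[list[Detection]]:
    """Decode the three raw maps into per-image Detection lists (input-space
    pixels); no NMS is applied here."""
    arrays = [p.data if isinstance(p, Tensor) else np.asarray(p) for p in preds]
    batch = arrays[0].shape[0]
    out: list[list[Detection]] = [[] for _ in range(batch)]
    for level, pred in enumerate(arrays):
        boxes, scores = decode_level(pred, cfg, level)
        best_cls = scores.argmax(axis=2)             # (N, 3, H, W)
        best_score = scores.max(axis=2)
        keep = np.argwhere(best_score > conf_threshold)
        for n, a, gy, gx in keep:
            x1, y1, x2, y2 = boxes[n, a, gy, gx]
            if x2 <= x1 or y2 <= y1:
                continue
            out[n].append(
                Detection(
                    box=(float(x1), float(y1), float(x2), float(y2)),
                    score=float(best_score[n, a, gy, gx]),
                    class_id=int(best_cls[n, a, gy, gx]),
                )
            )
    for dets in out:
        dets.sort(key=lambda d: -d.score)
    return out


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return np.log(p / (1 - p))


def encode_box(box_xyxy, class_id: int, cfg: ModelConfig, level: int,
               anchor_idx: int, grid_hw: tuple) -> tuple:
    """Inverse of :func:`decode_level` for one ground-truth box.

    Returns (gy, gx, raw_vector) such that writing ``raw_vector`` at cell
    (gy, gx), anchor ``anchor_idx`` and decoding reproduces the box.  Used by
    round-trip tests and target diagnostics.
    """
    stride = cfg.strides[level]
    x1, y1, x2, y2 = box_xyxy
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    bw, bh = x2 - x1, y2 - y1
    gi, gj = int(cx / stride), int(cy / stride)
    gi = min(max(gi, 0), grid_hw[1] - 1)
    gj = min(max(gj, 0), grid_hw[0] - 1)
    anchors = cfg.anchors_array()[level]
    raw = np.zeros(cfg.num_outputs, dtype=np.float32)
    raw[0] = _logit((cx / stride - gi + 0.5) / 2)
    raw[1] = _logit((cy / stride - gj + 0.5) / 2)
    raw[2] = _logit(np.sqrt(bw / anchors[anchor_idx, 0]) / 2)
    raw[3] = _logit(np.sqrt(bh / anchors[anchor_idx, 1]) / 2)
    raw[4] = 20.0  # objectness ~ 1
    raw[5:] = -20.0
    raw[5 + class_id] = 20.0
    return gj, gi, raw


# --------------------------------------------------------------- checkpoints
def save_checkpoint(model: Detector, path, extra: dict | None = None) -> None:
    """Serialize weights + config into a single ``.npz`` state file."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.cfg),
        "extra": extra or {},
    }
    state = model.state_dict()
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **state)


def load_checkpoint(path) -> tuple[Detector, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        cfg_dict = meta["config"]
        cfg_dict["anchors"] = tuple(tuple(tuple(a) for a in lvl) for lvl in cfg_dict["anchors"])
        cfg = ModelConfig(**cfg_dict)
        model = build_model(cfg)
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta["extra"]
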