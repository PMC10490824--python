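"""Dataset plumbing: YOLO-format labels, train/val split, letterboxing and
mosaic augmentation.

Label dialect: one object per line, ``class cx cy w h``, space-separated,
center coordinates and sizes normalized by the image dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from PIL import Image

PAD_VALUE = 114  # gray letterbox / mosaic fill


@dataclass(frozen=True)
class Annotation:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"annotation must have positive size: {self}")

    def to_xyxy(self, img_w: float, img_h: float) -> tuple:
        return (
            (self.cx - self.w / 2) * img_w,
            (self.cy - self.h / 2) * img_h,
            (self.cx + self.w / 2) * img_w,
            (self.cy + self.h / 2) * img_h,
        )

    @staticmethod
    def from_xyxy(class_id: int, x1, y1, x2, y2, img_w, img_h) -> "Annotation":
        return Annotation(
            class_id,
            (x1 + x2) / 2 / img_w,
            (y1 + y2) / 2 / img_h,
            (x2 - x1) / img_w,
            (y2 - y1) / img_h,
        )


class LabelParseError(ValueError):
    pass


def read_yolo_labels(path, num_classes: int | None = None) -> list[Annotation]:
    anns: list[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(
                    f"{path}:{lineno}: expected 'class cx cy w h', got {line!r}"
                )
            try:
                cid = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:])
            except ValueError as exc:
                raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
            if num_classes is not None and not 0 <= cid < num_classes:
                raise LabelParseError(
                    f"{path}:{lineno}: class id {cid} outside [0, {num_classes})"
                )
            anns.append(Annotation(cid, cx, cy, w, h))
    return anns


def write_yolo_labels(path, anns: list[Annotation]) -> None:
    with open(path, "w") as fh:
        for a in anns:
            fh.write(f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}\n")


@dataclass
class DatasetIndex:
    image_paths: list
    label_paths: list
    class_names: list
    split: str = "all"

    def __post_init__(self):
        if len(self.image_paths) != len(self.label_paths):
            raise ValueError("one label file per image required")

    def __len__(self):
        return len(self.image_paths)


def load_dataset_yaml(path) -> DatasetIndex:
    """Load a dataset descriptor: ``{root, images, labels, names}``."""
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    root = (path.parent / spec.get("root", ".")).resolve()
    img_dir = root / spec.get("images", "images")
    lbl_dir = root / spec.get("labels", "labels")
    images = sorted(
        p for p in img_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    labels = [lbl_dir / (p.stem + ".txt") for p in images]
    missing = [str(l) for l in labels if not l.exists()]
    if missing:
        raise FileNotFoundError(f"missing label files: {missing[:3]}")
    return DatasetIndex(list(images), labels, list(spec["names"]))


def split_dataset(index: DatasetIndex, ratio: float = 0.7,
                  seed: int = 0) -> tuple[DatasetIndex, DatasetIndex]:
    """Random disjoint train/val split; |train| = round(ratio * N)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(index)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    tr, va = order[:n_train], order[n_train:]

    def subset(idx, tag):
        return DatasetIndex(
            [index.image_paths[i] for i in idx],
            [index.label_paths[i] for i in idx],
            index.class_names,
            split=tag,
        )

    return subset(tr, "train"), subset(va, "val")


def load_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.ascontiguousarray(img[:, :, :3])


def _resize(img: np.ndarray, w: int, h: int) -> np.ndarray:
    return np.asarray(Image.fromarray(img).resize((w, h), Image.BILINEAR))


def letterbox(image: np.ndarray, target: int) -> tuple[np.ndarray, float, tuple]:
    """Scale preserving aspect ratio and pad to target x target with gray 114.

    Returns (canvas, scale, (pad_x, pad_y)); a source point p maps to
    p * scale + pad.
    """
    if target % 32:
        raise ValueError("letterbox target must be divisible by 32")
    h, w = image.shape[:2]
    scale = min(target / h, target / w)
    new_w, new_h = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    resized = _resize(image, new_w, new_h)
    canvas = np.full((target, target, 3), PAD_VALUE, dtype=image.dtype)
    pad_x, pad_y = (target - new_w) // 2, (target - new_h) // 2
    canvas[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = resized
    return canvas, scale, (pad_x, pad_y)


def unletterbox_box(box_xyxy, scale: float, pad: tuple) -> tuple:
    x1, y1, x2, y2 = box_xyxy
    px, py = pad
    return ((x1 - px) / scale, (y1 - py) / scale, (x2 - px) / scale, (y2 - py) / scale)


def mosaic_augment(samples, out_size: int, rng: np.random.Generator,
                   min_area_frac: float = 0.10) -> tuple[np.ndarray, list[Annotation]]:
    """Stitch 4 (image, annotations) samples into one out_size^2 image.

    A mosaic center is drawn uniformly in [0.25, 0.75] * out_size; each input
    is scaled by a factor in [0.5, 1.5] and laid out in its quadrant anchored
    at the center.  Boxes are mapped by the tile affine transform, clipped to
    the visible region, and dropped if the clip removes >90% of their area.
    """
    if len(samples) != 4:
        raise ValueError("mosaic requires exactly 4 samples")
    s = out_size
    xc = int(rng.uniform(0.25, 0.75) * s)
    yc = int(rng.uniform(0.25, 0.75) * s)
    canvas = np.full((s, s, 3), PAD_VALUE, dtype=np.uint8)
    out_anns: list[Annotation] = []
    for tile, (img, anns) in enumerate(samples):
        h0, w0 = img.shape[:2]
        scale = rng.uniform(0.5, 1.5) * s / max(h0, w0)
        nw, nh = max(1, int(w0 * scale)), max(1, int(h0 * scale))
        resized = _resize(img, nw, nh)
        if tile == 0:   # top-left: bottom-right corner at center
            x1a, y1a = max(xc - nw, 0), max(yc - nh, 0)
            x2a, y2a = xc, yc
            x1b, y1b = nw - (x2a - x1a), nh - (y2a - y1a)
        elif tile == 1:  # top-right
            x1a, y1a = xc, max(yc - nh, 0)
            x2a, y2a = min(xc + nw, s), yc
            x1b, y1b = 0, nh - (y2a - y1a)
        elif tile == 2:  # bottom-left
            x1a, y1a = max(xc - nw, 0), yc
            x2a, y2a = xc, min(yc + nh, s)
            x1b, y1b = nw - (x2a - x1a), 0
        else:            # bottom-right
            x1a, y1a = xc, yc
            x2a, y2a = min(xc + nw, s), min(yc + nh, s)
            x1b, y1b = 0, 0
        x2b, y2b = x1b + (x2a - x1a), y1b + (y2a - y1a)
        canvas[y1a:y2a, x1a:x2a] = resized[y1b:y2b, x1b:x2b]
        dx, dy = x1a - x1b, y1a - y1b  # tile affine: p_out = p_in*scale + (dx,dy)
        for a in anns:
            bx1, by1, bx2, by2 = a.to_xyxy(w0, h0)
            bx1, by1 = bx1 * scale + dx, by1 * scale + dy
            bx2, by2 = bx2 * scale + dx, by2 * scale + dy
            area0 = (bx2 - bx1) * (by2 - by1)
            cx1, cy1 = max(bx1, x1a), max(by1, y1a)
            cx2, cy2 = min(bx2, x2a), min(by2, y2a)
            if cx2 <= cx1 or cy2 <= cy1:
                continue
            if (cx2 - cx1) * (cy2 - cy1) < min_area_frac * area0:
                continue
            out_anns.append(Annotation.from_xyxy(a.class_id, cx1, cy1, cx2, cy2, s, s))
    return canvas, out_anns


def annotations_to_array(anns: list[Annotation]) -> np.ndarray:
    """(n, 5) array of (class, cx, cy, w, h), normalized."""
    if not anns:
        return np.zeros((0, 5), dtype=np.float32)
    return np.asarray(
        [(a.class_id, a.cx, a.cy, a.w, a.h) for a in anns], dtype=np.float32
    )


class DetectionDataset:
    """Batch provider for training/validation.

    Yields (images NCHW float32 in [0,1], list of per-image (n,5) gt arrays).
    Mosaic (when enabled) replaces each sample by a 4-image stitch drawn from
    the same index.
    """

    def __init__(self, index: DatasetIndex, input_size: int,
                 mosaic: bool = False, rng: np.random.Generator | None = None):
        self.index = index
        self.input_size = input_size
        self.mosaic = mosaic
        self.rng = rng or np.random.default_rng(0)
        self._cache: dict[int, tuple] = {}

    def _load(self, i: int):
        if i not in self._cache:
            img = load_image(self.index.image_paths[i])
            anns = read_yolo_labels(
                self.index.label_paths[i], num_classes=len(self.index.class_names)
            )
            self._cache[i] = (img, anns)
        return self._cache[i]

    def sample(self, i: int) -> tuple[np.ndarray, list[Annotation]]:
        if self.mosaic:
            picks = [i] + list(self.rng.integers(0, len(self.index), 3))
            return mosaic_augment(
                [self._load(j) for j in picks], self.input_size, self.rng
            )
        img, anns = self._load(i)
        canvas, scale, (px, py) = letterbox(img, self.input_size)
        h, w = img.shape[:2]
        mapped = []
        for a in anns:
            x1, y1, x2, y2 = a.to_xyxy(w, h)
            mapped.append(
                Annotation.from_xyxy(
                    a.class_id, x1 * scale + px, y1 * scale + py,
                    x2 * scale + px, y2 * scale + py,
                    self.input_size, self.input_size,
                )
            )
        return canvas, mapped

    def batches(self, batch_size: int, shuffle: bool = True):
        order = (
            self.rng.permutation(len(self.index))
            if shuffle
            else np.arange(len(self.index))
        )
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            imgs, gts = [], []
            for i in idx:
                img, anns = self.sample(int(i))
                imgs.append(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
                gts.append(annotations_to_array(anns))
            yield np.stack(imgs), gts
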