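"""Synthetic bone-marrow-smear image generator.

Emulates the statistical structure of Wright-stained marrow aspirate crops:
600 x 600 RGB tiles with a pink textured plasma background and dense,
partially overlapping cells.  Each cell is a rotated cytoplasm ellipse with a
darker, roughly concentric nucleus; the 15 classes differ in hue, nucleus-to-
cell ratio and eccentricity so that they are learnable by a detector.  Object
bounding boxes are the tight axis-aligned boxes of the cytoplasm ellipse,
written as normalized YOLO labels.

The defaults encode the source dataset's statistics: ~11 cells per image
(13,059 cells / 1,204 images), object width/height around 9% of the image
side, and a long-tailed class distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import stats
from skimage.draw import ellipse as draw_ellipse

from .data import Annotation, DatasetIndex, write_yolo_labels

CLASS_NAMES = [
    "blast", "promyelocyte", "N-myelocyte", "N-metamyelocyte", "N-band",
    "N-segmented", "eosinophil", "basophil", "lymphocyte", "monocyte",
    "proerythroblast", "basophilic-erythroblast", "polychromatic-erythroblast",
    "orthochromatic-erythroblast", "smudge-cell",
]

# long-tailed class frequencies (mature neutrophils/lymphocytes dominate)
_DEFAULT_CLASS_COUNTS = np.array(
    [3, 4, 6, 7, 9, 18, 2, 1, 14, 3, 2, 4, 10, 8, 2], dtype=np.float64
)

# Per-class appearance: (cytoplasm RGB, nucleus RGB, nucleus/cell area ratio,
# min aspect ratio).  Hues span a wide wheel and shape parameters are
# decorrelated from color so the 15 classes are learnable by a detector;
# realism is secondary to separability here.
def _class_styles():
    import colorsys

    styles = []
    for i in range(15):
        hue = (0.83 + i / 15.0) % 1.0          # start near pink, walk the wheel
        cyto = np.array(colorsys.hsv_to_rgb(hue, 0.45, 0.92)) * 255
        nucl = np.array(colorsys.hsv_to_rgb((hue + 0.5) % 1.0, 0.65, 0.45)) * 255
        nuc_ratio = 0.25 + 0.55 * ((i * 7) % 15) / 14.0
        min_aspect = 0.55 + 0.40 * ((i * 11) % 15) / 14.0
        styles.append((cyto, nucl, nuc_ratio, min_aspect))
    return styles


_CLASS_STYLE = _class_styles()


@dataclass
class SmearSpec:
    image_size: int = 600
    num_classes: int = 15
    cells_per_image: float = 11.0      # Poisson mean
    size_mean: float = 0.09            # box side as fraction of image side
    size_sd: float = 0.02
    size_bounds: tuple = (0.03, 0.25)
    overlap_allowed: bool = True
    max_pair_overlap: float = 0.30     # max pairwise box IoU when placing
    class_weights: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CLASS_COUNTS / _DEFAULT_CLASS_COUNTS.sum()
    )

    def __post_init__(self):
        self.class_weights = np.asarray(self.class_weights, dtype=np.float64)
        if len(self.class_weights) != self.num_classes:
            raise ValueError("class_weights length must equal num_classes")
        if not np.isclose(self.class_weights.sum(), 1.0):
            raise ValueError("class_weights must sum to 1")
        lo, hi = self.size_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("size bounds must lie in (0, 1)")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([233, 215, 222], dtype=np.float32)  # pale pink plasma
    coarse = rng.normal(0.0, 6.0, (size // 16 + 2, size // 16 + 2, 3)).astype(np.float32)
    texture = np.kron(coarse, np.ones((16, 16, 1), dtype=np.float32))[:size, :size]
    fine = rng.normal(0.0, 2.5, (size, size, 3)).astype(np.float32)
    return np.clip(base + texture + fine, 0, 255)


def _sample_size_fraction(spec: SmearSpec, rng: np.random.Generator) -> float:
    lo, hi = spec.size_bounds
    a = (lo - spec.size_mean) / spec.size_sd
    b = (hi - spec.size_mean) / spec.size_sd
    return float(
        stats.truncnorm.rvs(a, b, loc=spec.size_mean, scale=spec.size_sd,
                            random_state=rng)
    )


def _box_iou(b1, b2) -> float:
    iw = max(0.0, min(b1[2], b2[2]) - max(b1[0], b2[0]))
    ih = max(0.0, min(b1[3], b2[3]) - max(b1[1], b2[1]))
    inter = iw * ih
    a1 = (b1[2] - b1[0]) * (b1[3] - b1[1])
    a2 = (b2[2] - b2[0]) * (b2[3] - b2[1])
    return inter / max(a1 + a2 - inter, 1e-12)


def generate_image(spec: SmearSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[Annotation]]:
    """Render one smear tile and its annotations (deterministic given rng)."""
    size = spec.image_size
    img = _background(size, rng)
    n_cells = int(rng.poisson(spec.cells_per_image))
    anns: list[Annotation] = []
    placed_boxes: list[tuple] = []
    for _ in range(n_cells):
        cid = int(rng.choice(spec.num_classes, p=spec.class_weights))
        cyto_base, nucl_base, nuc_ratio, min_aspect = _CLASS_STYLE[cid]
        for _attempt in range(50):
            frac = _sample_size_fraction(spec, rng)
            a_semi = frac * size / 2.0
            aspect = rng.uniform(min_aspect, 1.0)
            b_semi = a_semi * aspect
            theta = rng.uniform(0, np.pi)
            half_w = np.sqrt((a_semi * np.cos(theta)) ** 2 + (b_semi * np.sin(theta)) ** 2)
            half_h = np.sqrt((a_semi * np.sin(theta)) ** 2 + (b_semi * np.cos(theta)) ** 2)
            cx = rng.uniform(half_w + 1, size - half_w - 1)
            cy = rng.uniform(half_h + 1, size - half_h - 1)
            box = (cx - half_w, cy - half_h, cx + half_w, cy + half_h)
            limit = spec.max_pair_overlap if spec.overlap_allowed else 0.0
            if all(_box_iou(box, other) <= limit for other in placed_boxes):
                break
        else:
            continue  # crowded image: skip this cell
        placed_boxes.append(box)
        cyto = cyto_base + rng.normal(0, 5, 3)
        nucl = nucl_base + rng.normal(0, 5, 3)
        rr, cc = draw_ellipse(cy, cx, b_semi, a_semi, shape=(size, size),
                              rotation=theta)
        img[rr, cc] = 0.85 * cyto + 0.15 * img[rr, cc]
        off = rng.normal(0, a_semi * 0.08, 2)
        rr, cc = draw_ellipse(
            cy + off[0], cx + off[1], b_semi * nuc_ratio ** 0.5,
            a_semi * nuc_ratio ** 0.5, shape=(size, size),
            rotation=theta + rng.normal(0, 0.2),
        )
        img[rr, cc] = 0.9 * nucl + 0.1 * img[rr, cc]
        anns.append(
            Annotation(
                cid,
                cx / size,
                cy / size,
                2 * half_w / size,
                2 * half_h / size,
            )
        )
    return img.astype(np.uint8), anns


def generate_dataset(spec: SmearSpec, n_images: int, out_dir,
                     seed: int = 0, force: bool = False) -> DatasetIndex:
    """Write ``n_images`` PNG tiles + YOLO labels + a dataset YAML."""
    out = Path(out_dir)
    img_dir, lbl_dir = out / "images", out / "labels"
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    image_paths, label_paths = [], []
    for i in range(n_images):
        img, anns = generate_image(spec, rng)
        ip = img_dir / f"smear_{i:05d}.png"
        lp = lbl_dir / f"smear_{i:05d}.txt"
        iio.imwrite(ip, img)
        write_yolo_labels(lp, anns)
        image_paths.append(ip)
        label_paths.append(lp)
    with open(out / "dataset.yaml", "w") as fh:
        yaml.safe_dump(
            {"root": ".", "images": "images", "labels": "labels",
             "names": CLASS_NAMES[: spec.num_classes], "seed": seed},
            fh, sort_keys=False,
        )
    return DatasetIndex(image_paths, label_paths, CLASS_NAMES[: spec.num_classes])
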