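"""Training loop, validation mAP, and inference entry points.

The optimizer is momentum SGD (momentum 0.937, weight decay 5e-4 on conv
weights only) with a cosine learning-rate schedule from ``lr0`` and a linear
warmup.  Per-epoch losses and validation mAP@0.5 are logged to CSV; the
best-mAP and last checkpoints are saved.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import DatasetIndex, DetectionDataset, letterbox, load_image, unletterbox_box
from .evaluation import evaluate_matches, match_detections, merge_matches
from .losses import ComputeLoss, FocalParams, LossWeights
from .model import (
    Detection,
    Detector,
    ModelConfig,
    build_model,
    decode_predictions,
    load_checkpoint,
    save_checkpoint,
)
from .nn import SGD, split_decay_groups
from .postprocess import NMSConfig, ciou_nms

from . import __version__


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 4
    momentum: float = 0.937
    weight_decay: float = 0.0005
    lr0: float = 0.01
    lr_final_frac: float = 0.1
    warmup_epochs: int = 3
    seed: int = 0
    mosaic: bool = True
    max_iters: int | None = None  # hard cap on optimizer steps (smoke runs)
    eval_every: int = 1           # epochs between validation evaluations
    eval_conf_threshold: float = 0.1
    ema_decay: float = 0.995      # weight EMA; 0 disables (last.npz = raw)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def _lr_at(step: int, total_steps: int, warmup_steps: int, cfg: TrainConfig) -> float:
    if warmup_steps and step < warmup_steps:
        return cfg.lr0 * (step + 1) / warmup_steps
    t = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
    cos = 0.5 * (1 + np.cos(np.pi * min(t, 1.0)))
    return cfg.lr0 * (cfg.lr_final_frac + (1 - cfg.lr_final_frac) * cos)


def evaluate_model(model: Detector, dataset: DetectionDataset,
                   nms_cfg: NMSConfig, iou_thr: float = 0.5) -> dict:
    """Run inference over a dataset and compute mAP@0.5 in input space."""
    model.eval()
    results = []
    with ag.no_grad():
        for imgs, gts in dataset.batches(batch_size=2, shuffle=False):
            preds = model(Tensor(imgs))
            decoded = decode_predictions(preds, model.cfg,
                                         conf_threshold=nms_cfg.conf_threshold)
            for dets, g in zip(decoded, gts):
                kept = ciou_nms(dets, nms_cfg)
                size = dataset.input_size
                gt_rows = [
                    (
                        int(c),
                        (cx - w / 2) * size, (cy - h / 2) * size,
                        (cx + w / 2) * size, (cy + h / 2) * size,
                    )
                    for c, cx, cy, w, h in g
                ]
                results.append(match_detections(kept, gt_rows, iou_thr=iou_thr))
    return evaluate_matches(merge_matches(results))


def train(train_cfg: TrainConfig, model_cfg: ModelConfig, index: DatasetIndex,
          out_dir, val_index: DatasetIndex | None = None,
          loss_weights: LossWeights | None = None,
          focal: FocalParams | None = None,
          nms_cfg: NMSConfig | None = None,
          soft_obj: bool = True, obj_gain: float = 1.0) -> dict:
    """Train a detector; returns a summary dict (losses, best mAP, paths)."""
    if len(index) == 0:
        raise ValueError("empty training dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(model_cfg, seed=train_cfg.seed)
    criterion = ComputeLoss(model_cfg, weights=loss_weights, focal=focal,
                            soft_obj=soft_obj, obj_gain=obj_gain)
    optimizer = SGD(
        split_decay_groups(model, train_cfg.weight_decay),
        lr=train_cfg.lr0, momentum=train_cfg.momentum,
    )
    dataset = DetectionDataset(index, model_cfg.input_size,
                               mosaic=train_cfg.mosaic, rng=rng)
    val_ds = DetectionDataset(val_index or index, model_cfg.input_size, mosaic=False)
    nms_cfg = nms_cfg or NMSConfig(conf_threshold=train_cfg.eval_conf_threshold)

    steps_per_epoch = int(np.ceil(len(index) / train_cfg.batch_size))
    total_steps = train_cfg.epochs * steps_per_epoch
    if train_cfg.max_iters is not None:
        total_steps = min(total_steps, train_cfg.max_iters)
    warmup = train_cfg.warmup_epochs * steps_per_epoch

    meta = {
        "seed": train_cfg.seed,
        "version": __version__,
        "train_config": asdict(train_cfg),
    }
    history: list[dict] = []
    first_loss = None
    last_loss = None
    best_map = -1.0
    step = 0
    # exponential moving average of the weights (the deployed model); the
    # decay ramps in so early noisy steps are quickly forgotten
    ema_state = (
        {k: v.copy() for k, v in model.state_dict().items()}
        if train_cfg.ema_decay > 0
        else None
    )
    t0 = time.time()
    csv_path = out / "metrics.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "step", "box_loss", "cls_loss", "obj_loss",
                         "total_loss", "lr", "val_map50"])
        for epoch in range(train_cfg.epochs):
            if step >= total_steps:
                break
            model.train()
            epoch_losses = []
            for imgs, gts in dataset.batches(train_cfg.batch_size, shuffle=True):
                if step >= total_steps:
                    break
                lr = _lr_at(step, total_steps, warmup, train_cfg)
                optimizer.lr = lr
                preds = model(Tensor(imgs))
                total, breakdown = criterion(preds, gts)
                optimizer.zero_grad()
                total.backward()
                optimizer.step()
                loss_val = float(total.data)
                if first_loss is None:
                    first_loss = loss_val
                last_loss = loss_val
                epoch_losses.append(
                    (breakdown.box_loss, breakdown.cls_loss, breakdown.obj_loss,
                     loss_val)
                )
                if ema_state is not None:
                    d = train_cfg.ema_decay * (1 - np.exp(-(step + 1) / 200))
                    for k, v in model.state_dict().items():
                        ema_state[k] = d * ema_state[k] + (1 - d) * v
                step += 1
            if not epoch_losses:
                continue
            mean_losses = np.mean(np.asarray(epoch_losses), axis=0)
            do_eval = ((epoch + 1) % max(train_cfg.eval_every, 1) == 0
                       or step >= total_steps)
            val = evaluate_model(model, val_ds, nms_cfg) if do_eval else None
            writer.writerow(
                [epoch, step, *(f"{v:.5f}" for v in mean_losses),
                 f"{optimizer.lr:.5f}",
                 f"{val['map50']:.5f}" if val else ""]
            )
            fh.flush()
            history.append({"epoch": epoch, "loss": float(mean_losses[3]),
                            "map50": val["map50"] if val else None})
            if val and val["map50"] > best_map:
                best_map = val["map50"]
                save_checkpoint(model, out / "best.npz",
                                extra={**meta, "epoch": epoch, "map50": best_map})
    if ema_state is not None:
        model.load_state_dict(ema_state)
    save_checkpoint(model, out / "last.npz", extra={**meta, "steps": step})
    summary = {
        "first_loss": first_loss,
        "last_loss": last_loss,
        "best_map50": best_map,
        "steps": step,
        "wall_seconds": time.time() - t0,
        "history": history,
        "metrics_csv": str(csv_path),
        "best_checkpoint": str(out / "best.npz"),
        "last_checkpoint": str(out / "last.npz"),
        **meta,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def detect(checkpoint_path, image_paths, nms_cfg: NMSConfig = NMSConfig(),
           num_classes: int | None = None) -> list[dict]:
    """Run inference on images; detections in source-image pixel coordinates."""
    model, extra = load_checkpoint(checkpoint_path)
    if num_classes is not None and num_classes != model.cfg.num_classes:
        raise ValueError(
            f"class-count mismatch: requested {num_classes}, "
            f"checkpoint has {model.cfg.num_classes}"
        )
    model.eval()
    out = []
    with ag.no_grad():
        for path in image_paths:
            img = load_image(path)
            canvas, scale, pad = letterbox(img, model.cfg.input_size)
            x = Tensor(canvas.transpose(2, 0, 1)[None].astype(np.float32) / 255.0)
            preds = model(x)
            dets = decode_predictions(preds, model.cfg,
                                      conf_threshold=nms_cfg.conf_threshold)[0]
            kept = ciou_nms(dets, nms_cfg)
            mapped = []
            for d in kept:
                x1, y1, x2, y2 = unletterbox_box(d.box, scale, pad)
                mapped.append(
                    {"box": [x1, y1, x2, y2], "score": d.score,
                     "class_id": d.class_id}
                )
            out.append({"image": str(path), "detections": mapped,
                        "seed": extra.get("seed"), "version": __version__})
    return out
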