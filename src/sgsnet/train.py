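"""Deterministic desk-scale training and evaluation loop.

Plain SGD with momentum and weight decay, a linear warmup of both learning
rate and momentum over the first epochs, and the weighted composite
detection loss.  Every source of randomness (init, data order) is seeded,
so two runs with the same seed produce identical loss traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .head import (InnerIoUConfig, LossBreakdown, assign_targets,
                   composite_loss, decode_and_nms)
from .evaluate import MetricReport, map_at_05
from .model import SGSNet
from .synthetic import LabeledImage

__all__ = ["TrainConfig", "warmup_schedule", "train", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published recipe)."""

    momentum: float = 0.937
    initial_lr: float = 0.01
    final_lr: float = 0.01
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    warmup_lr: float = 0.1          # multiplier on initial_lr at warmup start
    image_size: int = 640
    batch_size: int = 16
    optimizer: str = "SGD"
    iou_train_threshold: float = 0.2
    anchor_match_threshold: float = 5.0
    box_weight: float = 7.5
    cls_weight: float = 0.5
    obj_weight: float = 0.7
    dfl_weight: float = 1.5
    inner_iou_ratio: float = 0.75
    seed: int = 0

    def loss_weights(self) -> dict:
        return {"box": self.box_weight, "cls": self.cls_weight,
                "obj": self.obj_weight, "dfl": self.dfl_weight}


def warmup_schedule(step: int, total_warmup_steps: int,
                    cfg: TrainConfig) -> tuple[float, float]:
    """(lr, momentum) at optimizer step ``step``.

    Linear interpolation from (warmup_lr * initial_lr, warmup_momentum) at
    step 0 to (initial_lr, momentum) at the end of warmup; constant at the
    final learning rate afterwards.
    """
    if total_warmup_steps < 1:
        raise ValueError("total_warmup_steps must be >= 1")
    if step >= total_warmup_steps:
        return cfg.final_lr, cfg.momentum
    t = step / total_warmup_steps
    lr0 = cfg.warmup_lr * cfg.initial_lr
    return (lr0 + t * (cfg.initial_lr - lr0),
            cfg.warmup_momentum + t * (cfg.momentum - cfg.warmup_momentum))


class _SGD:
    def __init__(self, params, cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float, momentum: float):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.cfg.weight_decay * p.data
            v *= momentum
            v += g
            p.data -= lr * v
            p.grad = None


def _image_targets(img: LabeledImage):
    return [(b.class_id, b.corners(img.width, img.height)) for b in img.boxes]


def train(model: SGSNet, dataset: list[LabeledImage], cfg: TrainConfig,
          iterations: int, log_every: int = 0) -> list[LossBreakdown]:
    """Run ``iterations`` SGD steps over ``dataset`` and return the loss trace.

    Batches cycle through a seeded shuffle of the dataset each epoch.  A
    non-finite loss aborts with a diagnostic.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    model.set_training(True)
    opt = _SGD(model.parameters(), cfg)
    steps_per_epoch = max(1, int(np.ceil(len(dataset) / cfg.batch_size)))
    total_warmup = max(1, int(round(cfg.warmup_epochs * steps_per_epoch)))
    inner_cfg = InnerIoUConfig(cfg.inner_iou_ratio)
    trace: list[LossBreakdown] = []
    order: list[int] = []
    for it in range(iterations):
        while len(order) < cfg.batch_size:
            order += list(rng.permutation(len(dataset)))
        batch_idx, order = order[:cfg.batch_size], order[cfg.batch_size:]
        batch = [dataset[i] for i in batch_idx]
        x = Tensor(np.concatenate([model.preprocess(im.pixels) for im in batch]))
        gts = [_image_targets(im) for im in batch]
        preds = model(x)
        assignment = assign_targets(preds, gts, cfg.image_size,
                                    iou_floor=cfg.iou_train_threshold)
        loss = composite_loss(preds, assignment, inner_cfg, cfg.loss_weights())
        if not np.isfinite(loss.total):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: {loss.as_dict()}")
        loss.total_tensor.backward()
        lr, mom = warmup_schedule(it, total_warmup, cfg)
        opt.step(lr, mom)
        loss.total_tensor = None        # release the tape
        model._last_neck_feats = None
        trace.append(loss)
        if log_every and (it + 1) % log_every == 0:
            print(f"iter {it + 1:5d}  lr {lr:.5f}  " +
                  "  ".join(f"{k} {v:.4f}" for k, v in loss.as_dict().items()))
    return trace


def evaluate(model: SGSNet, dataset: list[LabeledImage],
             conf_thr: float = 0.001, nms_iou: float = 0.7,
             iou_thr: float = 0.5) -> MetricReport:
    """Decode + NMS on every image, then pooled per-class AP and mAP@0.5."""
    if not dataset:
        raise ValueError("empty dataset")
    from ._tensor import no_grad
    model.set_training(False)
    dets_all, gts_all = [], []
    with no_grad():
        for img in dataset:
            x = Tensor(model.preprocess(img.pixels))
            dets = decode_and_nms(model(x), conf_thr, nms_iou)[0]
            dets_all.append(dets)
            gts_all.append(_image_targets(img))
    return map_at_05(dets_all, gts_all, iou_thr=iou_thr)
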