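"""Detection metrics, the model-complexity audit and Grad-CAM++ heatmaps.

Metrics follow the usual detection conventions: greedy score-ordered
matching of detections to same-class ground truths at an IoU threshold,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean, AP the
area under the precision envelope of the PR staircase (all-point
interpolation), and mAP@0.5 the unweighted mean of per-class APs over
classes with at least one annotated instance.

The audit walks the architecture graph analytically, summing
K_h*K_w*C_in*C_out parameters per convolution and the same quantity times
the output map area as FLOPs (multiply–accumulate convention, divided by
1e9 for GFLOPs), with normalization, attention and resampling terms
itemized separately.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .head import Detection, iou_matrix
from .synthetic import STAGE_NAMES

__all__ = ["MetricReport", "AuditReport", "match_detections",
           "precision_recall_f1", "average_precision", "map_at_05",
           "audit_model", "gradcam_pp"]


# ---------------------------------------------------------------------------
# Matching and scalar metrics
# ---------------------------------------------------------------------------

def match_detections(dets: list[Detection], gts, iou_thr: float = 0.5):
    """Greedy matching of score-descending detections to ground truths.

    ``gts`` is a list of (class_id, xyxy).  Returns (labels, n_unmatched_gt)
    where ``labels[i]`` is True for a TP.  Each ground truth matches at most
    one detection: the highest-IoU unmatched same-class one at or above the
    threshold.
    """
    labels = np.zeros(len(dets), bool)
    used = np.zeros(len(gts), bool)
    gt_boxes = np.array([g[1] for g in gts], float).reshape(-1, 4)
    for di, det in enumerate(dets):
        best_iou, best_gi = 0.0, -1
        for gi, (gcls, _) in enumerate(gts):
            if used[gi] or gcls != det.class_id:
                continue
            iou = iou_matrix(det.xyxy[None], gt_boxes[gi][None])[0, 0]
            if iou >= iou_thr and iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0:
            labels[di] = True
            used[best_gi] = True
    return labels, int((~used).sum())


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P, R and F1 with the 0/0 -> 0 convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def average_precision(scores, labels, n_gt: int) -> float:
    """Area under the precision envelope of the PR staircase.

    ``scores``/``labels`` are parallel sequences (label True = TP); ``n_gt``
    the number of ground truths.  With no ground truths the AP is defined
    as 0.
    """
    if n_gt <= 0:
        return 0.0
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, integrated over recall (all-point interpolation)
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


@dataclass
class MetricReport:
    per_class: dict                # name -> {precision, recall, f1, ap, n_gt, tp, fp, fn}
    map50: float

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["stage", "precision", "recall", "f1", "ap", "n_gt"])
            for name, row in self.per_class.items():
                wr.writerow([name, f"{row['precision']:.4f}", f"{row['recall']:.4f}",
                             f"{row['f1']:.4f}", f"{row['ap']:.4f}", row["n_gt"]])
            wr.writerow(["mAP@0.5", f"{self.map50:.4f}", "", "", "", ""])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"per_class": self.per_class, "mAP@0.5": self.map50},
                      fh, indent=2)


def map_at_05(dets_per_image, gts_per_image, classes=STAGE_NAMES,
              iou_thr: float = 0.5) -> MetricReport:
    """Pooled-dataset per-class AP and their unweighted mean.

    ``dets_per_image``: list of per-image Detection lists; ``gts_per_image``:
    list of per-image lists of (class_id, xyxy).  Classes without any ground
    truth are reported but excluded from the mean.
    """
    per_class = {}
    aps = []
    for ci, name in enumerate(classes):
        scores, labels = [], []
        n_gt = fn = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            cd = [d for d in dets if d.class_id == ci]
            cg = [g for g in gts if g[0] == ci]
            lab, miss = match_detections(sorted(cd, key=lambda d: -d.score),
                                         cg, iou_thr)
            scores += [d.score for d in sorted(cd, key=lambda d: -d.score)]
            labels += lab.tolist()
            n_gt += len(cg)
            fn += miss
        tp = int(np.sum(labels))
        fp = len(labels) - tp
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        ap = average_precision(scores, labels, n_gt)
        per_class[name] = {"precision": p, "recall": r, "f1": f1, "ap": ap,
                           "n_gt": n_gt, "tp": tp, "fp": fp, "fn": fn}
        if n_gt > 0:
            aps.append(ap)
    return MetricReport(per_class, float(np.mean(aps)) if aps else 0.0)


# ---------------------------------------------------------------------------
# Complexity audit
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    layers: list                   # dicts: name, kind, params, flops
    total_params: int
    total_flops: int
    input_size: int

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    def by_kind(self) -> dict:
        out: dict = {}
        for rec in self.layers:
            d = out.setdefault(rec["kind"], {"params": 0, "flops": 0})
            d["params"] += rec["params"]
            d["flops"] += rec["flops"]
        return out

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["name", "kind", "params", "flops"])
            for rec in self.layers:
                wr.writerow([rec["name"], rec["kind"], rec["params"], rec["flops"]])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"input_size": self.input_size,
                       "total_params": self.total_params,
                       "total_flops": self.total_flops,
                       "params_M": self.params_m, "gflops": self.gflops,
                       "by_kind": self.by_kind()}, fh, indent=2)


def audit_model(model, input_size: int = 640) -> AuditReport:
    """Analytic parameter/FLOP walk of a full detector at a concrete input
    size (the model itself is not executed)."""
    if input_size % 32:
        raise ValueError("input size must be divisible by 32")
    recs = model.audit_records(input_size)
    clean = [{"name": r["name"], "kind": r["kind"], "params": int(r["params"]),
              "flops": int(r["flops"])} for r in recs]
    return AuditReport(clean, sum(r["params"] for r in clean),
                       sum(r["flops"] for r in clean), input_size)


# ---------------------------------------------------------------------------
# Grad-CAM++
# ---------------------------------------------------------------------------

def gradcam_pp(model, image: np.ndarray, class_id: int,
               layer: str = "p3") -> np.ndarray:
    """Class-discriminative heatmap for one image.

    The class score is the sum over cells of the class logit (weighted by
    objectness probability); channel weights use the closed-form
    second/third-order coefficients
    ``alpha = g^2 / (2 g^2 + sum(A) g^3)`` applied to ReLU'd gradients, and
    the map ``ReLU(sum_k w_k A^k)`` is min–max normalized and bilinearly
    resized to the input resolution.  Returns an (H, W) float array in
    [0, 1]; an all-zero gradient field yields an all-zero map.
    """
    from PIL import Image as _Image

    h_in, w_in = image.shape[:2]
    x = Tensor(model.preprocess(image))
    model.set_training(False)
    feats, score = model.class_score(x, class_id, layer)
    feats.zero_grad()
    score.backward()
    if feats.grad is None or not np.any(feats.grad):
        return np.zeros((h_in, w_in), np.float32)
    a = feats.data[0]                       # (C, h, w)
    g = feats.grad[0]
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + a.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1, denom), 0.0)
    w_k = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    cam = np.maximum((w_k[:, None, None] * a).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    im = _Image.fromarray((cam * 255).astype(np.uint8))
    cam = np.asarray(im.resize((w_in, h_in), _Image.BILINEAR), np.float32) / 255.0
    return cam
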