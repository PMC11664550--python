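"""Full detector assembly: backbone -> neck -> heads, plus config and
checkpoint plumbing.

Two architecture presets ship with the package as YAML files under
``configs/``: ``sgsnet_full.yaml`` — the frozen full-size configuration
whose audited complexity matches the published model budget — and
``sgsnet_tiny.yaml``, a desk-scale preset used by the tests and the
training demonstrations.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
import json
from dataclasses import dataclass

import numpy as np
import yaml

from ._tensor import Tensor, no_grad
from .backbone import BackboneConfig, GrowthNet, PyramidFeatures
from .head import DetectionHead, RawPrediction
from .layers import Module
from .neck import Neck, NeckConfig

__all__ = ["ModelConfig", "SGSNet", "load_config", "builtin_config"]

N_CLASSES = 5


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig
    neck: NeckConfig
    head_hidden: int | None = None
    n_classes: int = N_CLASSES

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(
            backbone=BackboneConfig.from_dict(d["backbone"]),
            neck=NeckConfig.from_dict(d["neck"]),
            head_hidden=d.get("head_hidden"),
            n_classes=d.get("n_classes", N_CLASSES))

    def to_dict(self) -> dict:
        return {"backbone": self.backbone.to_dict(),
                "neck": self.neck.to_dict(),
                "head_hidden": self.head_hidden,
                "n_classes": self.n_classes}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str) -> ModelConfig:
    with open(path) as fh:
        return ModelConfig.from_dict(yaml.safe_load(fh))


def builtin_config(name: str = "full") -> ModelConfig:
    """Load a packaged architecture preset: 'full' or 'tiny'."""
    ref = resources.files("sgsnet.configs") / f"sgsnet_{name}.yaml"
    return ModelConfig.from_dict(yaml.safe_load(ref.read_text()))


class SGSNet(Module):
    """The detector: GrowthNet backbone, fusion neck, anchor-free heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = GrowthNet(config.backbone, rng)
        self.neck = Neck(self.backbone.out_channels, config.neck, rng)
        self.head = DetectionHead(self.neck.out_channels, config.n_classes,
                                  rng, hidden=config.head_hidden)
        self._last_neck_feats = None

    def forward(self, x: Tensor) -> RawPrediction:
        pyr = self.backbone(x)
        n3, n4, n5 = self.neck(pyr)
        self._last_neck_feats = {"p3": n3, "p4": n4, "p5": n5}
        return self.head((n3, n4, n5))

    def set_deploy(self, mode: bool = True):
        self.neck.set_deploy(mode)
        return self

    # -- audit --------------------------------------------------------------
    def audit_records(self, input_size: int):
        recs, _, _ = self.backbone.audit_records(input_size, input_size)
        h3 = input_size // 8
        recs = recs + self.neck.audit_records(h3, h3)
        recs = recs + self.head.audit_records(h3, h3)
        return recs

    # -- inference helpers --------------------------------------------------
    @staticmethod
    def preprocess(image: np.ndarray) -> np.ndarray:
        """HWC uint8 -> (1, 3, H, W) float32 in [0, 1]."""
        x = np.asarray(image, np.float32) / 255.0
        return x.transpose(2, 0, 1)[None]

    def predict(self, image: np.ndarray, conf_thr: float = 0.25,
                nms_iou: float = 0.7):
        from .head import decode_and_nms
        self.set_training(False)
        with no_grad():
            preds = self.forward(Tensor(self.preprocess(image)))
        return decode_and_nms(preds, conf_thr, nms_iou)[0]

    def class_score(self, x: Tensor, class_id: int, layer: str = "p3"):
        """Scalar class evidence and the neck feature map it flows through
        (for Grad-CAM++): objectness-weighted class logits, summed over the
        chosen level's cells."""
        preds = self.forward(x)
        feats = self._last_neck_feats[layer]
        li = {"p3": 0, "p4": 1, "p5": 2}[layer]
        score = (preds.cls[li][:, class_id] * preds.obj[li][:, 0].sigmoid()).sum()
        return feats, score

    # -- checkpoints ---------------------------------------------------------
    def save_checkpoint(self, path: str) -> None:
        """Write an ``.npz`` checkpoint.

        Key schema: one array per trainable parameter, named by its module
        path (e.g. ``backbone.stem.conv.weight``,
        ``neck.fuse3.irmb.q.weight``, ``head.cls_convs.0.bias``), plus a
        ``__meta__`` byte array holding the JSON-encoded architecture config
        and its digest.
        """
        state = self.state_dict()
        meta = {"config": self.config.to_dict(), "digest": self.config.digest()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)

    @staticmethod
    def load_checkpoint(path: str) -> "SGSNet":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = SGSNet(ModelConfig.from_dict(meta["config"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model
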