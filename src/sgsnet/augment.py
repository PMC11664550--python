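"""Photometric and geometric augmentation, applied jointly to pixels and boxes.

Three photometric operators act directly on RGB values and never move boxes:

* brightness: ``v -> clip(v + s, 0, 255)``
* darkness:   ``v -> clip(v - s, 0, 255)``
* chroma:     ``v -> clip(v + s * (v - g), 0, 255)`` with ``g`` the per-pixel
  mean of the three channels (saturation gain about the gray axis)

Geometric operators reflect pixels and remap boxes: a horizontal flip maps
``cx -> 1 - cx``, a vertical flip ``cy -> 1 - cy``.  ``mirror`` is kept as a
separate catalog entry producing the same transform as a horizontal flip, so
expansion multiplicities stay configurable per operator name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import Box, LabeledImage


@dataclass(frozen=True)
class PhotometricParams:
    """Operator intensities; defaults give clearly visible but unsaturated shifts."""

    s_brightness: float = 40.0
    s_darkness: float = 40.0
    s_chroma: float = 0.4

    def __post_init__(self):
        if self.s_brightness < 0 or self.s_darkness < 0:
            raise ValueError("brightness/darkness intensities must be >= 0")


def _clip_u8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def adjust_brightness(img: LabeledImage, s: float) -> LabeledImage:
    if s < 0:
        raise ValueError("s must be >= 0")
    px = _clip_u8(img.pixels.astype(np.float32) + s)
    return LabeledImage(px, list(img.boxes), img.image_id, img.seed)


def adjust_darkness(img: LabeledImage, s: float) -> LabeledImage:
    if s < 0:
        raise ValueError("s must be >= 0")
    px = _clip_u8(img.pixels.astype(np.float32) - s)
    return LabeledImage(px, list(img.boxes), img.image_id, img.seed)


def adjust_chroma(img: LabeledImage, s: float) -> LabeledImage:
    x = img.pixels.astype(np.float32)
    g = x.mean(axis=2, keepdims=True)
    px = _clip_u8(x + s * (x - g))
    return LabeledImage(px, list(img.boxes), img.image_id, img.seed)


def flip(img: LabeledImage, axis: str) -> LabeledImage:
    if axis == "horizontal":
        px = np.ascontiguousarray(img.pixels[:, ::-1])
        boxes = [Box(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in img.boxes]
    elif axis == "vertical":
        px = np.ascontiguousarray(img.pixels[::-1])
        boxes = [Box(b.class_id, b.cx, 1.0 - b.cy, b.w, b.h) for b in img.boxes]
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    return LabeledImage(px, boxes, img.image_id, img.seed)


def mirror(img: LabeledImage) -> LabeledImage:
    """Mirroring: a horizontal reflection kept as its own catalog entry."""
    return flip(img, "horizontal")


# the default catalog: the original image plus these five operators -> 6x
DEFAULT_CATALOG = ("flip_vertical", "mirror", "brightness", "darkness", "chroma")


def apply_operator(img: LabeledImage, name: str,
                   params: PhotometricParams = PhotometricParams()) -> LabeledImage:
    if name == "flip_horizontal":
        out = flip(img, "horizontal")
    elif name == "flip_vertical":
        out = flip(img, "vertical")
    elif name == "mirror":
        out = mirror(img)
    elif name == "brightness":
        out = adjust_brightness(img, params.s_brightness)
    elif name == "darkness":
        out = adjust_darkness(img, params.s_darkness)
    elif name == "chroma":
        out = adjust_chroma(img, params.s_chroma)
    else:
        raise ValueError(f"unknown operator {name!r}")
    out.image_id = f"{img.image_id}__{name}"
    return out


def augment_dataset(images: list[LabeledImage],
                    operators=DEFAULT_CATALOG,
                    params: PhotometricParams = PhotometricParams()) -> list[LabeledImage]:
    """Expand a dataset: originals followed by every operator applied to each."""
    out = list(images)
    for img in images:
        for name in operators:
            out.append(apply_operator(img, name, params))
    return out
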