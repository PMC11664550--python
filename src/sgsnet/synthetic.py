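"""Synthetic stage-labelled strawberry scenes and annotation plumbing.

Real greenhouse imagery of the five strawberry growth stages is not
publicly distributable, so the test harness renders caricature scenes:
elliptical fruit/flower bodies with achene speckles and a calyx wedge on a
textured green background, one tight bounding box per object.  The five
phenotypes follow the field descriptions of the stages:

* ``Flowering`` – white petals with a yellow center;
* ``Young Fruit`` – small green fruit;
* ``Fruit Expansion`` – larger, pale-white fruit;
* ``Color Turning`` – pink fruit with a partial red patch;
* ``Maturation`` – plump, saturated red fruit.

These are deliberately simple visual caricatures used to exercise the
detector end to end; they make no biological claim.

The module also reads/writes the two annotation dialects used in practice
(YOLO txt with normalized centers, Pascal VOC XML with 1-based inclusive
pixel corners), letterbox-resizes images, and produces deterministic
train/test/val splits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from lxml import etree
from PIL import Image

STAGE_NAMES = ("Flowering", "Young Fruit", "Fruit Expansion",
               "Color Turning", "Maturation")
N_STAGES = 5

# per-stage body palette (RGB) and radius range as a fraction of image size
_STAGE_BODY = {
    0: (245, 244, 238),   # white petals
    1: (110, 165, 70),    # small green fruit
    2: (226, 221, 200),   # pale white
    3: (232, 118, 130),   # pink
    4: (190, 24, 36),     # saturated red
}
_STAGE_SPECKLE = {
    0: (250, 208, 60),    # yellow flower center disc (drawn as speckles+core)
    1: (70, 115, 45),
    2: (185, 172, 95),
    3: (215, 195, 120),
    4: (235, 205, 90),
}
_STAGE_RADIUS = {          # (lo, hi) of the semi-major axis / image size
    0: (0.030, 0.050),
    1: (0.018, 0.032),
    2: (0.040, 0.065),
    3: (0.040, 0.065),
    4: (0.045, 0.072),
}
_CALYX = (60, 125, 50)
_PAD_GRAY = 114


class AnnotationError(ValueError):
    """Malformed annotation content (carries the offending line number)."""


@dataclass(frozen=True)
class Box:
    """One annotated object in normalized YOLO-style coordinates."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (0 <= self.class_id < N_STAGES):
            raise ValueError(f"class_id {self.class_id} outside 0..{N_STAGES - 1}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite {name}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extent must be positive")

    def clipped(self) -> "Box":
        """Clip the box to the unit square, preserving the class."""
        x0 = min(max(self.cx - self.w / 2, 0.0), 1.0)
        x1 = min(max(self.cx + self.w / 2, 0.0), 1.0)
        y0 = min(max(self.cy - self.h / 2, 0.0), 1.0)
        y1 = min(max(self.cy + self.h / 2, 0.0), 1.0)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("box entirely outside the image")
        return Box(self.class_id, (x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0)

    def corners(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Absolute (x0, y0, x1, y1) in pixel units (0-based, exclusive)."""
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)


@dataclass
class LabeledImage:
    pixels: np.ndarray            # H x W x 3 uint8
    boxes: list[Box]
    image_id: str
    seed: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SplitManifest:
    train: list[str]
    test: list[str]
    val: list[str]
    fractions: tuple[float, float, float]

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        for name in ("train", "test", "val"):
            with open(os.path.join(directory, f"{name}.txt"), "w") as fh:
                fh.write("".join(f"{i}\n" for i in getattr(self, name)))

    @staticmethod
    def load(directory: str) -> "SplitManifest":
        parts = {}
        for name in ("train", "test", "val"):
            with open(os.path.join(directory, f"{name}.txt")) as fh:
                parts[name] = [ln.strip() for ln in fh if ln.strip()]
        n = sum(len(v) for v in parts.values())
        fr = tuple(len(parts[k]) / n for k in ("train", "test", "val"))
        return SplitManifest(parts["train"], parts["test"], parts["val"], fr)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def render_scene(seed: int, stage_mix=None, n_objects: int = 4,
                 size: int = 640) -> LabeledImage:
    """Render one synthetic scene with ``n_objects`` stage-labelled objects.

    ``stage_mix`` is a probability vector over the five stages (uniform when
    omitted).  Identical arguments yield byte-identical output.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    if size < 64:
        raise ValueError("size must be >= 64")
    mix = np.full(N_STAGES, 1.0 / N_STAGES) if stage_mix is None else np.asarray(stage_mix, float)
    if mix.shape != (N_STAGES,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("stage_mix must be a length-5 probability vector")
    rng = np.random.default_rng(seed)

    # textured leafy-green background: base color + low-frequency blotches + noise
    img = np.empty((size, size, 3), np.float32)
    base = np.array([46, 98, 44], np.float32)
    small = rng.uniform(-1, 1, (size // 16 + 1, size // 16 + 1))
    blotch = np.kron(small, np.ones((16, 16)))[:size, :size]
    for ch, amp in enumerate((10.0, 16.0, 8.0)):
        img[..., ch] = base[ch] + amp * blotch
    img += rng.normal(0.0, 6.0, (size, size, 3))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    boxes: list[Box] = []
    classes = rng.choice(N_STAGES, size=n_objects, p=mix)
    for k in range(n_objects):
        c = int(classes[k])
        lo, hi = _STAGE_RADIUS[c]
        a = rng.uniform(lo, hi) * size                  # semi-axis x
        b = a * rng.uniform(0.85, 1.15)                 # semi-axis y
        cx = rng.uniform(a + 2, size - a - 2)
        cy = rng.uniform(b + 2, size - b - 2)
        body = np.asarray(_STAGE_BODY[c], np.float32) + rng.uniform(-12, 12, 3)
        d2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
        mask = d2 <= 1.0
        # radial shading for a little realism
        shade = 1.0 - 0.25 * d2
        img[mask] = body[None, :] * shade[mask, None]

        obj_mask = mask.copy()
        if c == 0:
            # flower: yellow center disc
            core = d2 <= 0.12
            img[core] = np.asarray(_STAGE_SPECKLE[0], np.float32)
        else:
            # achene speckles inside the body
            n_spk = max(4, int(a * b / 28))
            th = rng.uniform(0, 2 * np.pi, n_spk)
            rr = np.sqrt(rng.uniform(0, 0.82, n_spk))
            sx = (cx + rr * a * np.cos(th)).astype(int)
            sy = (cy + rr * b * np.sin(th)).astype(int)
            spk = np.asarray(_STAGE_SPECKLE[c], np.float32)
            for px, py in zip(sx, sy):
                img[max(py - 1, 0):py + 1, max(px - 1, 0):px + 1] = spk
            if c == 3:
                # color turning: partial red patch on one flank
                patch = mask & (xx - cx > 0.15 * a)
                img[patch] = np.asarray([200, 44, 60], np.float32) * shade[patch, None]
        # calyx wedge above the body
        cal_h = 0.45 * b
        cal = (np.abs(xx - cx) <= 0.35 * a * (yy - (cy - b - cal_h)) / max(cal_h, 1e-6)) \
            & (yy >= cy - b - cal_h) & (yy <= cy - 0.55 * b)
        img[cal] = np.asarray(_CALYX, np.float32)
        obj_mask |= cal

        ys, xs = np.nonzero(obj_mask)
        x0, x1 = xs.min(), xs.max() + 1
        y0, y1 = ys.min(), ys.max() + 1
        boxes.append(Box(c, (x0 + x1) / 2 / size, (y0 + y1) / 2 / size,
                         (x1 - x0) / size, (y1 - y0) / size).clipped())

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(pixels, boxes, image_id=f"scene_{seed:08d}", seed=seed)


def render_dataset(n_images: int, seed: int, stage_mix=None,
                   n_objects_range: tuple[int, int] = (1, 12),
                   size: int = 640) -> list[LabeledImage]:
    """Render ``n_images`` scenes with per-scene object counts drawn uniformly."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        n_obj = int(rng.integers(n_objects_range[0], n_objects_range[1] + 1))
        sub = int(rng.integers(0, 2**31 - 1))
        img = render_scene(sub, stage_mix=stage_mix, n_objects=n_obj, size=size)
        img.image_id = f"scene_{i:05d}_{sub:08d}"
        out.append(img)
    return out


# ---------------------------------------------------------------------------
# Annotation dialects
# ---------------------------------------------------------------------------

def write_annotations(img: LabeledImage, dialect: str, path: str) -> None:
    """Write ``img``'s boxes as YOLO txt or Pascal VOC XML."""
    if dialect == "yolo_txt":
        with open(path, "w") as fh:
            for b in img.boxes:
                fh.write(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n")
    elif dialect == "voc_xml":
        root = etree.Element("annotation")
        etree.SubElement(root, "filename").text = f"{img.image_id}.png"
        sz = etree.SubElement(root, "size")
        etree.SubElement(sz, "width").text = str(img.width)
        etree.SubElement(sz, "height").text = str(img.height)
        etree.SubElement(sz, "depth").text = "3"
        for b in img.boxes:
            obj = etree.SubElement(root, "object")
            etree.SubElement(obj, "name").text = STAGE_NAMES[b.class_id]
            bb = etree.SubElement(obj, "bndbox")
            x0, y0, x1, y1 = b.corners(img.width, img.height)
            # 1-based inclusive integer corners
            etree.SubElement(bb, "xmin").text = str(int(round(x0)) + 1)
            etree.SubElement(bb, "ymin").text = str(int(round(y0)) + 1)
            etree.SubElement(bb, "xmax").text = str(int(round(x1)))
            etree.SubElement(bb, "ymax").text = str(int(round(y1)))
        etree.ElementTree(root).write(path, pretty_print=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_annotations(path: str, dialect: str,
                     image_size: tuple[int, int] | None = None) -> list[Box]:
    """Inverse of :func:`write_annotations` up to coordinate quantization.

    ``image_size`` (width, height) is only needed for the VOC dialect when
    the XML lacks a ``size`` block.
    """
    boxes: list[Box] = []
    if dialect == "yolo_txt":
        with open(path) as fh:
            for ln_no, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise AnnotationError(f"line {ln_no}: expected 5 fields, got {len(parts)}")
                try:
                    cid = int(parts[0])
                    vals = [float(p) for p in parts[1:]]
                except ValueError as exc:
                    raise AnnotationError(f"line {ln_no}: {exc}") from None
                if not (0 <= cid < N_STAGES):
                    raise AnnotationError(f"line {ln_no}: class {cid} outside 0..{N_STAGES - 1}")
                if any(v < 0 or v > 1 for v in vals):
                    raise AnnotationError(f"line {ln_no}: coordinate outside [0,1]")
                boxes.append(Box(cid, *vals))
        return boxes
    if dialect == "voc_xml":
        root = etree.parse(path).getroot()
        sz = root.find("size")
        if sz is not None:
            width = int(sz.findtext("width"))
            height = int(sz.findtext("height"))
        elif image_size is not None:
            width, height = image_size
        else:
            raise AnnotationError("VOC file has no <size> and no image_size given")
        for idx, obj in enumerate(root.findall("object"), start=1):
            name = obj.findtext("name")
            if name not in STAGE_NAMES:
                raise AnnotationError(f"object {idx}: unknown class token {name!r}")
            bb = obj.find("bndbox")
            xmin = int(bb.findtext("xmin")) - 1     # back to 0-based
            ymin = int(bb.findtext("ymin")) - 1
            xmax = int(bb.findtext("xmax"))
            ymax = int(bb.findtext("ymax"))
            boxes.append(Box(STAGE_NAMES.index(name),
                             (xmin + xmax) / 2 / width, (ymin + ymax) / 2 / height,
                             (xmax - xmin) / width, (ymax - ymin) / height))
        return boxes
    raise ValueError(f"unknown dialect {dialect!r}")


def save_image(img: LabeledImage, path: str) -> None:
    Image.fromarray(img.pixels).save(path)


def load_image(path: str, image_id: str | None = None) -> LabeledImage:
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    iid = image_id or os.path.splitext(os.path.basename(path))[0]
    return LabeledImage(pixels, [], image_id=iid)


# ---------------------------------------------------------------------------
# Splits and resizing
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(ids: list[str], fractions=(0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitManifest:
    """Shuffle and partition ``ids`` into train/test/val.

    Per-part counts are round-half-up of n*fraction; any rounding residue is
    absorbed by the training part, so e.g. 7528 ids at (0.8, 0.1, 0.1) give
    (6022, 753, 753).
    """
    if not ids:
        raise ValueError("empty id list")
    fr = tuple(float(f) for f in fractions)
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    counts = [_round_half_up(n * f) for f in fr]
    counts[0] += n - sum(counts)
    if min(counts) < 0:
        raise ValueError("fractions produce a negative part size")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    a, b = counts[0], counts[0] + counts[1]
    return SplitManifest(order[:a], order[a:b], order[b:], fr)


def resize_letterbox(img: LabeledImage, target: int = 640) -> LabeledImage:
    """Aspect-preserving resize with symmetric gray padding to target²."""
    h, w = img.height, img.width
    scale = target / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    resized = np.asarray(
        Image.fromarray(img.pixels).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((target, target, 3), _PAD_GRAY, np.uint8)
    top, left = (target - nh) // 2, (target - nw) // 2
    canvas[top:top + nh, left:left + nw] = resized
    boxes = []
    for b in img.boxes:
        boxes.append(Box(b.class_id,
                         (b.cx * nw + left) / target, (b.cy * nh + top) / target,
                         b.w * nw / target, b.h * nh / target).clipped())
    return LabeledImage(canvas, boxes, image_id=img.image_id, seed=img.seed)
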