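"""Dataset tooling: Pascal VOC I/O, the small-target filter, Mosaic/Mixup
augmentation and the synthetic scene generator.

Internally boxes are continuous corner-form pixel arrays ``(x1, y1, x2, y2)``
with a half-open convention: a VOC object with 1-based inclusive corners
``(xmin, ymin, xmax, ymax)`` maps to ``(xmin - 1, ymin - 1, xmax, ymax)``,
so its width is ``xmax - xmin + 1`` pixels, and the mapping round-trips
exactly for integer corners.

The scene generator emulates the pasture footage the face detector targets:
wide frames holding many small (8-55 px) two-tone textured "faces" with eye
dots, placed singly or in clusters, under variable global illumination and
sensor noise.  It emits exact annotations and is fully seed-deterministic.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .boxes import Box

SMALL_TARGET_MAX_SIDE = 50.0
MOSAIC_MIN_BOX_AREA = 8.0  # px^2 surviving after clipping
FILL_VALUE = 114


class VocParseError(ValueError):
    pass


@dataclass
class Annotation:
    """Ground truth for one image: corner-form boxes plus labels."""

    image_id: str
    size: tuple[int, int]                  # (width, height)
    boxes: np.ndarray                      # (n, 4) corner form, continuous px
    labels: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None      # per-box mixing weights

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        if not self.labels:
            self.labels = ["goat_face"] * len(self.boxes)
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise ValueError("image size must be positive")
        if self.weights is None:
            self.weights = np.ones(len(self.boxes))

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)

    def side_lengths(self) -> np.ndarray:
        """(n, 2) widths and heights."""
        return np.stack([self.boxes[:, 2] - self.boxes[:, 0],
                         self.boxes[:, 3] - self.boxes[:, 1]], axis=1) if len(self.boxes) else np.zeros((0, 2))

    def max_sides(self) -> np.ndarray:
        return self.side_lengths().max(axis=1) if len(self.boxes) else np.zeros(0)

    def to_center_form(self) -> np.ndarray:
        b = self.boxes
        return np.stack([(b[:, 0] + b[:, 2]) / 2, (b[:, 1] + b[:, 3]) / 2,
                         b[:, 2] - b[:, 0], b[:, 3] - b[:, 1]], axis=1) if len(b) else np.zeros((0, 4))

    def to_boxes(self) -> list[Box]:
        return [Box.from_corners(*row) for row in self.boxes]

    def clipped(self) -> "Annotation":
        w, h = self.size
        b = self.boxes.copy()
        b[:, 0::2] = np.clip(b[:, 0::2], 0, w)
        b[:, 1::2] = np.clip(b[:, 1::2], 0, h)
        keep = (b[:, 2] > b[:, 0]) & (b[:, 3] > b[:, 1])
        return replace(self, boxes=b[keep],
                       labels=[l for l, k in zip(self.labels, keep) if k],
                       weights=self.weights[keep])


# ---- Pascal VOC ----------------------------------------------------------

def read_voc(path) -> Annotation:
    """Parse one VOC 2007 XML annotation file."""
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise VocParseError(f"malformed VOC XML in {path}: {exc}") from exc
    try:
        size = root.find("size")
        width = int(size.find("width").text)
        height = int(size.find("height").text)
        image_id = root.findtext("filename", default=path.stem)
        boxes, labels = [], []
        for obj in root.iter("object"):
            bb = obj.find("bndbox")
            xmin = float(bb.find("xmin").text)
            ymin = float(bb.find("ymin").text)
            xmax = float(bb.find("xmax").text)
            ymax = float(bb.find("ymax").text)
            boxes.append([xmin - 1.0, ymin - 1.0, xmax, ymax])
            labels.append(obj.findtext("name", default="goat_face"))
    except (AttributeError, TypeError, ValueError) as exc:
        raise VocParseError(f"invalid VOC structure in {path}: {exc}") from exc
    return Annotation(image_id=image_id, size=(width, height),
                      boxes=np.asarray(boxes, dtype=float).reshape(-1, 4),
                      labels=labels)


def write_voc(ann: Annotation, path) -> None:
    """Write an annotation back to VOC 2007 XML (1-based inclusive corners)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = ann.image_id
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.size[0])
    ET.SubElement(size, "height").text = str(ann.size[1])
    ET.SubElement(size, "depth").text = "3"
    for row, label in zip(ann.boxes, ann.labels):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(row[0])) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(row[1])) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(row[2])))
        ET.SubElement(bb, "ymax").text = str(int(round(row[3])))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


# ---- small-target filter -------------------------------------------------

@dataclass
class FilterReport:
    kept: int
    removed: list[tuple[str, float]]  # (image_id, offending max side)


def small_target_filter(annotations: list[Annotation],
                        max_side: float = SMALL_TARGET_MAX_SIDE,
                        level: str = "image") -> tuple[list[Annotation], FilterReport]:
    """Keep only small-target content.

    ``level='image'`` (dataset-construction rule): an image survives iff
    every box has max(w, h) <= max_side — sides of exactly ``max_side``
    survive.  ``level='box'`` instead drops oversized boxes individually.
    """
    kept, removed = [], []
    for ann in annotations:
        sides = ann.max_sides()
        if level == "image":
            if len(sides) and sides.max() > max_side:
                removed.append((ann.image_id, float(sides.max())))
            else:
                kept.append(ann)
        elif level == "box":
            sel = sides <= max_side if len(sides) else np.zeros(0, dtype=bool)
            if len(sides) and not sel.all():
                removed.append((ann.image_id, float(sides.max())))
            kept.append(replace(ann, boxes=ann.boxes[sel],
                                labels=[l for l, k in zip(ann.labels, sel) if k],
                                weights=ann.weights[sel]))
        else:
            raise ValueError("level must be 'image' or 'box'")
    return kept, FilterReport(kept=len(kept), removed=removed)


# ---- augmentation --------------------------------------------------------

def _resize(image: np.ndarray, out_wh: tuple[int, int]) -> np.ndarray:
    pil = Image.fromarray(image)
    return np.asarray(pil.resize(out_wh, Image.BILINEAR))


def mosaic(items: list[tuple[np.ndarray, Annotation]], out_size: int, seed: int,
           scale_range: tuple[float, float] = (0.5, 1.5),
           center_frac_range: tuple[float, float] = (0.25, 0.75),
           min_box_area: float = MOSAIC_MIN_BOX_AREA) -> tuple[np.ndarray, Annotation]:
    """Stitch four annotated images into one around a random center.

    Each source is randomly rescaled and placed so that its corner meets the
    mosaic center (top-left source at the center's top-left, and so on);
    overflow is cropped, underflow padded with the neutral fill value.
    Transformed boxes are clipped and dropped below ``min_box_area``.
    Deterministic for a fixed seed.
    """
    if len(items) != 4:
        raise ValueError("mosaic takes exactly four annotated images")
    rng = np.random.default_rng(seed)
    canvas = np.full((out_size, out_size, 3), FILL_VALUE, dtype=np.uint8)
    cx = int(out_size * rng.uniform(*center_frac_range))
    cy = int(out_size * rng.uniform(*center_frac_range))
    boxes, labels = [], []
    regions = [  # (x range, y range) of each quadrant on the canvas
        ((0, cx), (0, cy)), ((cx, out_size), (0, cy)),
        ((0, cx), (cy, out_size)), ((cx, out_size), (cy, out_size)),
    ]
    anchor_corner = [(1, 1), (0, 1), (1, 0), (0, 0)]  # which source corner sits at (cx, cy)
    for (img, ann), ((qx1, qx2), (qy1, qy2)), (ax, ay) in zip(items, regions, anchor_corner):
        scale = rng.uniform(*scale_range)
        sw = max(int(round(img.shape[1] * scale)), 1)
        sh = max(int(round(img.shape[0] * scale)), 1)
        scaled = _resize(img, (sw, sh))
        sx = scale * sw / (img.shape[1] * scale)  # exact per-axis scale after rounding
        sy = scale * sh / (img.shape[0] * scale)
        qw, qh = qx2 - qx1, qy2 - qy1
        if qw <= 0 or qh <= 0:
            continue
        # source placed so its (ax, ay) corner touches (cx, cy)
        ox = qx2 - sw if ax == 1 else qx1
        oy = qy2 - sh if ay == 1 else qy1
        src_x1, src_y1 = max(qx1 - ox, 0), max(qy1 - oy, 0)
        src_x2, src_y2 = min(qx2 - ox, sw), min(qy2 - oy, sh)
        if src_x2 <= src_x1 or src_y2 <= src_y1:
            continue
        dst_x1, dst_y1 = ox + src_x1, oy + src_y1
        canvas[dst_y1:dst_y1 + (src_y2 - src_y1), dst_x1:dst_x1 + (src_x2 - src_x1)] = \
            scaled[src_y1:src_y2, src_x1:src_x2]
        if ann.n_boxes:
            b = ann.boxes * np.array([sw / img.shape[1], sh / img.shape[0]] * 2)
            b[:, 0::2] += ox
            b[:, 1::2] += oy
            b[:, 0::2] = np.clip(b[:, 0::2], qx1, qx2)
            b[:, 1::2] = np.clip(b[:, 1::2], qy1, qy2)
            areas = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
            keep = areas >= min_box_area
            boxes.append(b[keep])
            labels.extend(l for l, k in zip(ann.labels, keep) if k)
    all_boxes = np.concatenate(boxes) if boxes else np.zeros((0, 4))
    out_ann = Annotation(image_id=f"mosaic_{seed}", size=(out_size, out_size),
                         boxes=all_boxes, labels=labels)
    return canvas, out_ann.clipped()


def mixup(a: tuple[np.ndarray, Annotation], b: tuple[np.ndarray, Annotation],
          lam: float | None = None, seed: int = 0) -> tuple[np.ndarray, Annotation]:
    """Blend two annotated images: ``lam * a + (1 - lam) * b``.

    The label set is the union of both images' boxes, each carrying its
    mixing ratio as a weight.  When ``lam`` is not given it is drawn from
    Beta(8, 8) (the YOLO-family convention).
    """
    img_a, ann_a = a
    img_b, ann_b = b
    if img_a.shape != img_b.shape:
        raise ValueError("mixup requires equal image shapes")
    if lam is None:
        lam = float(np.random.default_rng(seed).beta(8.0, 8.0))
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    blend = (lam * img_a.astype(float) + (1.0 - lam) * img_b.astype(float))
    blend = np.clip(np.round(blend), 0, 255).astype(np.uint8)
    if lam == 1.0:
        boxes, labels, weights = ann_a.boxes, list(ann_a.labels), np.ones(ann_a.n_boxes)
    elif lam == 0.0:
        boxes, labels, weights = ann_b.boxes, list(ann_b.labels), np.ones(ann_b.n_boxes)
    else:
        boxes = np.concatenate([ann_a.boxes, ann_b.boxes]) if ann_a.n_boxes + ann_b.n_boxes else np.zeros((0, 4))
        labels = list(ann_a.labels) + list(ann_b.labels)
        weights = np.concatenate([np.full(ann_a.n_boxes, lam),
                                  np.full(ann_b.n_boxes, 1.0 - lam)])
    ann = Annotation(image_id=f"mixup_{ann_a.image_id}_{ann_b.image_id}",
                     size=ann_a.size, boxes=boxes, labels=labels, weights=weights)
    return blend, ann


# ---- synthetic scenes ----------------------------------------------------

@dataclass
class SceneParams:
    """Parameters of the synthetic pasture-scene generator.

    Defaults emulate the study footage: 1920x1080 frames, a handful of
    small faces per frame (sides 8-55 px), optional clustering, daylight
    illumination varying over the day, and mild sensor noise.
    """

    image_size: tuple[int, int] = (1920, 1080)   # (width, height)
    n_faces: tuple[int, int] = (3, 12)           # inclusive range per scene
    face_side_range: tuple[float, float] = (8.0, 55.0)
    cluster_prob: float = 0.5
    illumination_range: tuple[float, float] = (0.55, 1.05)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.face_side_range[0] <= 0 or self.face_side_range[1] >= min(self.image_size):
            raise ValueError("face sides must fit inside the image")
        if self.face_side_range[0] > self.face_side_range[1]:
            raise ValueError("face_side_range must be (lo, hi) with lo <= hi")

    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size), "n_faces": list(self.n_faces),
            "face_side_range": list(self.face_side_range),
            "cluster_prob": self.cluster_prob,
            "illumination_range": list(self.illumination_range),
            "noise_sd": self.noise_sd, "seed": self.seed,
        }


def _background(rng: np.random.Generator, w: int, h: int) -> np.ndarray:
    """Low-frequency grass/dirt texture plus fine grain."""
    cw, ch = max(w // 64, 2), max(h // 64, 2)
    base = rng.uniform(0, 1, size=(ch, cw, 3))
    tones = np.array([[90, 110, 60], [120, 100, 70], [70, 90, 50]], dtype=float)
    coarse = base @ tones / base.sum(axis=2, keepdims=True).clip(1e-6)
    img = _resize(np.clip(coarse, 0, 255).astype(np.uint8), (w, h)).astype(float)
    img += rng.normal(0, 6, size=img.shape)
    return img


def _draw_face(img: np.ndarray, rng: np.random.Generator,
               cx: float, cy: float, fw: float, fh: float) -> None:
    """Render one two-tone elliptical face with eye dots, in place."""
    h_img, w_img = img.shape[:2]
    x1, y1 = int(np.floor(cx - fw / 2)), int(np.floor(cy - fh / 2))
    x2, y2 = int(np.ceil(cx + fw / 2)), int(np.ceil(cy + fh / 2))
    xs = np.arange(max(x1, 0), min(x2, w_img))
    ys = np.arange(max(y1, 0), min(y2, h_img))
    if not len(xs) or not len(ys):
        return
    gx, gy = np.meshgrid(xs + 0.5, ys + 0.5)
    u = (gx - cx) / (fw / 2)
    v = (gy - cy) / (fh / 2)
    inside = u**2 + v**2 <= 1.0
    coat = rng.uniform(140, 230)
    dark = coat * rng.uniform(0.45, 0.7)
    tone = np.where(v < -0.2, dark, coat)  # darker forehead band
    tone = tone + rng.normal(0, 5, size=tone.shape)  # pelt texture
    region = img[ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1]
    for c in range(3):
        chan = region[:, :, c]
        chan[inside] = tone[inside] * (0.9 + 0.1 * (c == 0))
    # eye dots at ~40% height
    for ex in (-0.35, 0.35):
        eye = (u - ex) ** 2 + (v + 0.1) ** 2 <= 0.012 + (0.05 / max(fw, 4.0))
        for c in range(3):
            chan = region[:, :, c]
            chan[eye & inside] = 25.0


def synth_scene(p: SceneParams) -> tuple[np.ndarray, Annotation]:
    """Render one annotated scene; bit-identical for a fixed seed."""
    rng = np.random.default_rng(p.seed)
    w, h = p.image_size
    img = _background(rng, w, h)
    n = int(rng.integers(p.n_faces[0], p.n_faces[1] + 1))
    boxes = []
    centers: list[tuple[float, float]] = []
    lo, hi = p.face_side_range
    margin = hi / 2 + 1
    attempts = 0
    while len(boxes) < n and attempts < n * 50:
        attempts += 1
        fw = rng.uniform(lo, hi)
        fh = min(fw * rng.uniform(1.0, 1.5), hi)
        if centers and rng.uniform() < p.cluster_prob:
            base = centers[rng.integers(len(centers))]
            cx = np.clip(base[0] + rng.normal(0, 3 * hi), margin, w - margin)
            cy = np.clip(base[1] + rng.normal(0, 3 * hi), margin, h - margin)
        else:
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
        cand = np.array([cx - fw / 2, cy - fh / 2, cx + fw / 2, cy + fh / 2])
        if boxes:
            prev = np.asarray(boxes)
            ix = np.clip(np.minimum(prev[:, 2], cand[2]) - np.maximum(prev[:, 0], cand[0]), 0, None)
            iy = np.clip(np.minimum(prev[:, 3], cand[3]) - np.maximum(prev[:, 1], cand[1]), 0, None)
            if np.any(ix * iy > 0.2 * fw * fh):
                continue
        _draw_face(img, rng, cx, cy, fw, fh)
        boxes.append(cand)
        centers.append((cx, cy))
    illum = rng.uniform(*p.illumination_range)
    img = img * illum
    if p.noise_sd > 0:
        img += rng.normal(0, p.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    ann = Annotation(image_id=f"scene_{p.seed}", size=(w, h),
                     boxes=np.asarray(boxes, dtype=float).reshape(-1, 4))
    return img, ann


def synth_dataset(p: SceneParams, n_scenes: int, out_dir) -> list[tuple[Path, Path]]:
    """Write ``n_scenes`` scenes (PNG + VOC XML) plus a manifest file.

    Scene ``i`` uses seed ``p.seed + i``.  Returns (image, xml) path pairs;
    the manifest lists them one tab-separated pair per line.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(n_scenes):
        sp = replace(p, seed=p.seed + i)
        img, ann = synth_scene(sp)
        img_path = out_dir / "images" / f"{ann.image_id}.png"
        xml_path = out_dir / "annotations" / f"{ann.image_id}.xml"
        Image.fromarray(img).save(img_path)
        write_voc(ann, xml_path)
        pairs.append((img_path, xml_path))
    with open(out_dir / "manifest.txt", "w") as fh:
        for img_path, xml_path in pairs:
            fh.write(f"{img_path}\t{xml_path}\n")
    return pairs


def read_manifest(path) -> list[tuple[Path, Path]]:
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        img_path, xml_path = line.split("\t")
        pairs.append((Path(img_path), Path(xml_path)))
    if not pairs:
        raise ValueError(f"empty dataset manifest: {path}")
    return pairs
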