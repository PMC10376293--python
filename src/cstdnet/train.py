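"""Training, evaluation and prediction entry points.

The training protocol mirrors the study defaults: batches of 8, AdamW at an
initial learning rate of 1e-4, 100 epochs with a checkpoint every 10.
Epoch counts, augmentation probabilities and the model scale are all
configurable, so the same loop drives both full-scale runs and the tiny
CPU overfit used in the test suite.

Checkpoints are self-describing ``.npz`` archives holding every weight and
batch-norm statistic plus a JSON header with the model, loss and anchor
configuration, so ``evaluate``/``predict`` need no external config.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .anchors import AnchorSet, assign_targets, default_small_target_anchors
from .boxes import LossConfig
from .data import Annotation, SceneParams, mixup, mosaic, read_manifest, read_voc, synth_scene
from .metrics import summarize
from .model import STRIDES, CSTDNet, ModelConfig, decode_predictions
from .nn import Tensor, autograd as ag
from .nn.losses import localization_loss
from .nn.modules import AdamW


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 1e-4
    optimizer: str = "adamw"
    epochs: int = 100
    checkpoint_every: int = 10
    seed: int = 0
    device: str = "cpu"
    weight_decay: float = 5e-4
    mosaic_prob: float = 0.5
    mixup_prob: float = 0.15
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    anchors: str = "small_target"   # small_target | yolov7 | kmeans

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs <= 0 or self.epochs % self.checkpoint_every:
            raise ValueError("checkpoint_every must divide a positive epoch budget")
        if self.optimizer != "adamw":
            raise ValueError("only the adamw optimizer is supported")

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size, "learning_rate": self.learning_rate,
            "optimizer": self.optimizer, "epochs": self.epochs,
            "checkpoint_every": self.checkpoint_every, "seed": self.seed,
            "device": self.device, "weight_decay": self.weight_decay,
            "mosaic_prob": self.mosaic_prob, "mixup_prob": self.mixup_prob,
            "loss": self.loss.to_dict(), "model": self.model.to_dict(),
            "anchors": self.anchors,
        }


class Dataset:
    """An in-memory annotated image collection at a fixed square size."""

    def __init__(self, items: list[tuple[np.ndarray, Annotation]]):
        if not items:
            raise ValueError("dataset is empty")
        self.items = items

    def __len__(self):
        return len(self.items)

    @classmethod
    def from_manifest(cls, manifest_path, input_size: int) -> "Dataset":
        items = []
        for img_path, xml_path in read_manifest(manifest_path):
            ann = read_voc(xml_path)
            img = np.asarray(Image.open(img_path).convert("RGB"))
            w, h = ann.size
            if (w, h) != (input_size, input_size):
                img = np.asarray(Image.fromarray(img).resize(
                    (input_size, input_size), Image.BILINEAR))
                boxes = ann.boxes * np.array([input_size / w, input_size / h] * 2)
                ann = replace(ann, size=(input_size, input_size), boxes=boxes)
            items.append((img, ann))
        return cls(items)

    @classmethod
    def from_scenes(cls, params: SceneParams, n_scenes: int) -> "Dataset":
        items = []
        for i in range(n_scenes):
            items.append(synth_scene(replace(params, seed=params.seed + i)))
        return cls(items)

    def all_boxes_wh(self) -> np.ndarray:
        sides = [ann.side_lengths() for _, ann in self.items if ann.n_boxes]
        return np.concatenate(sides) if sides else np.zeros((0, 2))

    def gt_map(self) -> dict[str, np.ndarray]:
        return {ann.image_id: ann.to_center_form() for _, ann in self.items}


def resolve_anchors(cfg: TrainConfig, dataset: Dataset | None = None) -> AnchorSet:
    if cfg.anchors == "small_target":
        return default_small_target_anchors()
    if cfg.anchors == "yolov7":
        from .anchors import yolov7_default_anchors
        return yolov7_default_anchors()
    if cfg.anchors == "kmeans":
        if dataset is None:
            raise ValueError("kmeans anchors need a dataset")
        from .anchors import anchor_set_from_boxes
        return anchor_set_from_boxes(dataset.all_boxes_wh(), seed=cfg.seed)
    raise ValueError(f"unknown anchor source {cfg.anchors!r}")


def _augmented_epoch(dataset: Dataset, cfg: TrainConfig,
                     rng: np.random.Generator) -> list[tuple[np.ndarray, Annotation]]:
    size = cfg.model.input_size
    items = []
    for img, ann in dataset.items:
        if cfg.mosaic_prob > 0 and rng.uniform() < cfg.mosaic_prob:
            picks = [dataset.items[j] for j in rng.integers(len(dataset), size=3)]
            img, ann = mosaic([(img, ann)] + picks, size,
                              seed=int(rng.integers(2**31)))
        if cfg.mixup_prob > 0 and rng.uniform() < cfg.mixup_prob:
            other = dataset.items[int(rng.integers(len(dataset)))]
            if other[0].shape == img.shape:
                img, ann = mixup((img, ann), other,
                                 seed=int(rng.integers(2**31)))
        items.append((img, ann))
    return items


def compute_loss(outputs, targets, anchors: AnchorSet, cfg: LossConfig,
                 num_classes: int) -> tuple[Tensor, dict[str, float]]:
    """Composite loss over the three head outputs.

    Objectness and class terms are binary cross entropy on logits (the
    sample weight multiplies both); the localization term is
    ``1 - <overlap variant>`` on the decoded positive boxes.
    """
    per_scale = anchors.per_scale
    conf_terms, cls_terms, loc_terms = [], [], []
    for out, stride in zip(outputs, STRIDES):
        t = targets[stride]
        n, ch, h, w = out.shape
        lvl_anchors = per_scale[stride]
        na = len(lvl_anchors)
        p = ag.reshape(out, (n, na, 5 + num_classes, h, w))
        obj_logits = p[:, :, 4]
        tgt_obj = np.zeros((n, na, h, w), dtype=out.data.dtype)
        if len(t):
            tgt_obj[t.img, t.anchor, t.gj, t.gi] = 1.0
        conf_terms.append(ag.tmean(ag.bce_with_logits(obj_logits, tgt_obj)))
        if len(t):
            pt = ag.transpose(p, (0, 1, 3, 4, 2))
            pos = pt[(t.img, t.anchor, t.gj, t.gi)]          # (P, 5 + nc)
            sxy = ag.sigmoid(pos[:, 0:2]) * 2.0 - 0.5
            swh = (ag.sigmoid(pos[:, 2:4]) * 2.0) ** 2
            grid = np.stack([t.gi, t.gj], axis=1).astype(float)
            cxy = (sxy + grid) * float(stride)
            wh = swh * lvl_anchors[t.anchor]
            pred = ag.concatenate([cxy, wh], axis=1)
            loc_terms.append(localization_loss(
                pred, t.box, variant=cfg.iou_variant.value,
                eps_combine=cfg.eps_combine.value))
            cls_logits = pos[:, 5:]
            tgt_cls = np.zeros((len(t), num_classes), dtype=out.data.dtype)
            tgt_cls[np.arange(len(t)), t.cls] = 1.0
            cls_terms.append(ag.tmean(ag.bce_with_logits(cls_logits, tgt_cls)))
    w_bce = cfg.bce_sample_weight
    l_conf = ag.mul(_mean_terms(conf_terms), w_bce)
    l_cls = ag.mul(_mean_terms(cls_terms), w_bce)
    l_loc = _mean_terms(loc_terms)
    total = cfg.w_conf * l_conf + cfg.w_cls * l_cls + cfg.w_loc * l_loc
    parts = {"conf": l_conf.item(), "cls": l_cls.item(), "loc": l_loc.item(),
             "total": total.item()}
    return total, parts


def _mean_terms(terms: list[Tensor]) -> Tensor:
    if not terms:
        return Tensor(np.zeros(()))
    acc = terms[0]
    for term in terms[1:]:
        acc = acc + term
    return ag.mul(acc, 1.0 / len(terms))


def _batch_tensor(items) -> Tensor:
    imgs = np.stack([img for img, _ in items]).astype(np.float32) / 255.0
    return Tensor(np.ascontiguousarray(imgs.transpose(0, 3, 1, 2)))


@dataclass
class TrainResult:
    history: list[dict]
    checkpoints: list[Path]
    anchors: AnchorSet
    model: CSTDNet


def train(cfg: TrainConfig, dataset: Dataset, out_dir) -> TrainResult:
    """Run the training loop; deterministic for a fixed seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    model = CSTDNet(cfg.model, seed=cfg.seed)
    anchors = resolve_anchors(cfg, dataset)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    history: list[dict] = []
    checkpoints: list[Path] = []
    size = cfg.model.input_size
    nc = cfg.model.num_classes
    log_path = out_dir / "loss_log.csv"
    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "total", "conf", "cls", "loc"])
        for epoch in range(1, cfg.epochs + 1):
            items = _augmented_epoch(dataset, cfg, rng)
            order = rng.permutation(len(items))
            epoch_parts = {"total": 0.0, "conf": 0.0, "cls": 0.0, "loc": 0.0}
            n_batches = 0
            model.train()
            for start in range(0, len(items), cfg.batch_size):
                batch = [items[i] for i in order[start:start + cfg.batch_size]]
                x = _batch_tensor(batch)
                outputs = model(x)
                targets = assign_targets(
                    [ann.to_center_form() for _, ann in batch], anchors, size)
                loss, parts = compute_loss(outputs, targets, anchors,
                                           cfg.loss, nc)
                opt.zero_grad()
                loss.backward()
                opt.step()
                for key in epoch_parts:
                    epoch_parts[key] += parts[key]
                n_batches += 1
            record = {k: v / n_batches for k, v in epoch_parts.items()}
            record["epoch"] = epoch
            history.append(record)
            writer.writerow([epoch, record["total"], record["conf"],
                             record["cls"], record["loc"]])
            if epoch % cfg.checkpoint_every == 0:
                ckpt = out_dir / f"checkpoint_epoch{epoch:04d}.npz"
                save_checkpoint(model, anchors, cfg, ckpt)
                checkpoints.append(ckpt)
    return TrainResult(history=history, checkpoints=checkpoints,
                       anchors=anchors, model=model)


# ---- checkpointing -------------------------------------------------------

def save_checkpoint(model: CSTDNet, anchors: AnchorSet, cfg: TrainConfig,
                    path) -> None:
    meta = {
        "model": model.cfg.to_dict(),
        "anchors": anchors.to_list(),
        "train": cfg.to_dict(),
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[CSTDNet, AnchorSet, dict]:
    archive = np.load(path)
    meta = json.loads(archive["__meta__"].tobytes().decode())
    model = CSTDNet(ModelConfig(**meta["model"]))
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    model.eval()
    anchors = AnchorSet(tuple(map(tuple, meta["anchors"])))
    return model, anchors, meta


# ---- evaluation / prediction --------------------------------------------

def detect(model: CSTDNet, anchors: AnchorSet, dataset: Dataset,
           conf_thresh: float = 0.001, nms_iou: float = 0.5,
           batch_size: int = 8):
    """Run inference over a dataset; returns a flat detection list."""
    model.eval()
    dets = []
    ids = [ann.image_id for _, ann in dataset.items]
    per_scale = anchors.per_scale
    anchor_list = [per_scale[s] for s in STRIDES]
    with ag.no_grad():
        for start in range(0, len(dataset), batch_size):
            batch = dataset.items[start:start + batch_size]
            outputs = model(_batch_tensor(batch))
            decoded = decode_predictions(
                outputs, anchor_list, conf_thresh=conf_thresh,
                nms_iou=nms_iou, image_ids=ids[start:start + len(batch)])
            for img_dets in decoded:
                dets.extend(img_dets)
    return dets


def evaluate(model: CSTDNet, anchors: AnchorSet, dataset: Dataset,
             iou_thresh: float = 0.7, conf_thresh: float = 0.5,
             nms_iou: float = 0.5) -> dict[str, float]:
    """P/R/F1 at the confidence cutoff plus threshold-free AP."""
    dets = detect(model, anchors, dataset, conf_thresh=0.001, nms_iou=nms_iou)
    return summarize(dets, dataset.gt_map(), iou_thresh=iou_thresh,
                     conf_thresh=conf_thresh)


def predict_images(model: CSTDNet, anchors: AnchorSet, image_paths,
                   conf_thresh: float = 0.25, nms_iou: float = 0.5,
                   overlay_dir=None):
    """Detect faces on image files; optionally write box overlays."""
    results = {}
    per_scale = anchors.per_scale
    anchor_list = [per_scale[s] for s in STRIDES]
    size = model.cfg.input_size
    for path in image_paths:
        path = Path(path)
        pil = Image.open(path).convert("RGB")
        w0, h0 = pil.size
        img = np.asarray(pil.resize((size, size), Image.BILINEAR))
        x = Tensor(img.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        with ag.no_grad():
            dets = decode_predictions(model(x), anchor_list,
                                      conf_thresh=conf_thresh, nms_iou=nms_iou,
                                      image_ids=[path.stem])[0]
        # map back to the original resolution
        sx, sy = w0 / size, h0 / size
        mapped = []
        for d in dets:
            b = d.box
            mapped.append(replace_box(d, b.cx * sx, b.cy * sy, b.w * sx, b.h * sy))
        results[path.stem] = mapped
        if overlay_dir is not None:
            overlay_dir = Path(overlay_dir)
            overlay_dir.mkdir(parents=True, exist_ok=True)
            draw_img = pil.copy()
            draw = ImageDraw.Draw(draw_img)
            for d in mapped:
                x1, y1, x2, y2 = d.box.to_corners()
                draw.rectangle([x1, y1, x2, y2], outline=(255, 40, 40), width=2)
                draw.text((x1, max(y1 - 10, 0)), f"{d.score:.2f}", fill=(255, 40, 40))
            draw_img.save(overlay_dir / f"{path.stem}_pred.png")
    return results


def replace_box(det, cx, cy, w, h):
    from .boxes import Box
    from .metrics import Detection
    return Detection(image_id=det.image_id,
                     box=Box(cx, cy, max(w, 1e-7), max(h, 1e-7)),
                     score=det.score, class_id=det.class_id)
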