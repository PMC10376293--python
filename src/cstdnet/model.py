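"""Assembly of the detection network and prediction decoding.

The model follows the one-stage anchor-based contract: a CSP-style backbone
tapped at strides 8/16/32, SPPCSPC on the deepest tap, a context/complement
neck (CIDM chain + two FCM blocks), and three convolutional heads.  Each
head emits ``anchors_per_scale * (4 + 1 + num_classes)`` channels — box
regression parameters, objectness, and class scores per anchor slot — so a
single-class model with 3 anchors per scale yields 18 channels, and a
640-pixel input yields 80x80 / 40x40 / 20x20 head maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import CIDM, FCMBlock, SPPCSPC, Backbone
from .boxes import Box
from .metrics import Detection
from .nn import Tensor, autograd as ag
from .nn.modules import Conv2d, ConvBNSiLU, Module

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class FeatureMapSpec:
    """(stride, channels, height, width) contract for one pyramid level."""

    stride: int
    channels: int
    height: int
    width: int

    def __post_init__(self):
        if self.stride not in STRIDES:
            raise ValueError(f"stride must be one of {STRIDES}")
        if min(self.channels, self.height, self.width) <= 0:
            raise ValueError("channels and spatial dims must be positive")


@dataclass
class ModelConfig:
    input_size: int = 640
    num_classes: int = 1
    anchors_per_scale: int = 3
    base_channels: int = 16
    eca_kernel: int | str = "adaptive"

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.base_channels % 4:
            raise ValueError("base_channels must be divisible by 4 (context branch split)")

    @property
    def head_channels(self) -> int:
        """Channels per head map: anchors x (4 box + 1 objectness + classes)."""
        return self.anchors_per_scale * (4 + 1 + self.num_classes)

    def head_specs(self, input_size: int | None = None) -> list[FeatureMapSpec]:
        size = self.input_size if input_size is None else input_size
        if size % 32:
            raise ValueError("input size must be divisible by 32")
        return [
            FeatureMapSpec(s, self.head_channels, size // s, size // s)
            for s in STRIDES
        ]

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size, "num_classes": self.num_classes,
            "anchors_per_scale": self.anchors_per_scale,
            "base_channels": self.base_channels, "eca_kernel": self.eca_kernel,
        }


class CSTDNet(Module):
    """Contextual small-target detection network.

    ``forward`` takes an NCHW image tensor (spatial size divisible by 32)
    and returns raw head tensors for strides 8, 16 and 32 in that order.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = Backbone(cfg.base_channels, rng)
        c3, c4, c5 = self.backbone.tap_channels
        self.spp = SPPCSPC(c5, c5, rng)
        ek = cfg.eca_kernel
        # middle level sees both neighbors; the pyramid ends drop one branch
        self.cidm_mid = CIDM(c4, rng, c_coarse=c5, c_fine=c3, eca_kernel=ek)
        self.cidm_fine = CIDM(c3, rng, c_coarse=c4, c_fine=None, eca_kernel=ek)
        self.cidm_coarse = CIDM(c5, rng, c_coarse=None, c_fine=c4, eca_kernel=ek)
        self.fcm_up = FCMBlock((c3, c4, c5), c3, c3, "up", rng)
        self.fcm_down = FCMBlock((c3, c4, c5), c3, c5, "down", rng)
        self.mid_conv = ConvBNSiLU(c4, c4, 3, rng)
        ho = cfg.head_channels
        self.head3 = Conv2d(c3, ho, 1, rng, bias=True)
        self.head4 = Conv2d(c4, ho, 1, rng, bias=True)
        self.head5 = Conv2d(c5, ho, 1, rng, bias=True)
        self._init_head_biases()

    def _init_head_biases(self):
        """Start objectness strongly negative so early confidence is low."""
        na, nc = self.cfg.anchors_per_scale, self.cfg.num_classes
        for head in (self.head3, self.head4, self.head5):
            b = head.bias.data.reshape(na, 5 + nc)
            b[:, 4] = -5.0
            head.bias.data = b.reshape(-1)

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        p3, p4, p5 = self.backbone(x)
        n5 = self.spp(p5)
        m4 = self.cidm_mid(p4, f_coarse=n5, f_fine=p3)
        m3 = self.cidm_fine(p3, f_coarse=m4)
        m5 = self.cidm_coarse(n5, f_fine=m4)
        out3 = self.head3(self.fcm_up(m3, m4, m5))
        out4 = self.head4(self.mid_conv(m4))
        out5 = self.head5(self.fcm_down(m3, m4, m5))
        return [out3, out4, out5]


def _nms(boxes_arr: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy non-maximum suppression on (n, 4) center-form boxes."""
    from .boxes import iou as box_iou

    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for pos, idx in enumerate(order):
        if suppressed[idx]:
            continue
        keep.append(int(idx))
        later = order[pos + 1:]
        later = later[~suppressed[later]]
        if len(later):
            overlaps = box_iou(np.broadcast_to(boxes_arr[idx], (len(later), 4)),
                               boxes_arr[later])
            suppressed[later[overlaps > iou_thresh]] = True
    return keep


def decode_predictions(outputs, anchor_pairs_per_level, conf_thresh: float = 0.25,
                       nms_iou: float = 0.5, image_ids=None,
                       max_det: int = 300) -> list[list[Detection]]:
    """Turn raw head tensors into scored detections.

    Cell offsets pass through ``2*sigmoid - 0.5``; sizes through
    ``(2*sigmoid)^2 * anchor`` (the YOLOv5-family decode).  Scores are
    ``sigmoid(objectness) * sigmoid(class)``; per-class greedy NMS follows.

    ``anchor_pairs_per_level`` is a sequence of three (3, 2) pixel arrays
    matching strides 8/16/32.
    """
    with ag.no_grad():
        raw = [o.data if isinstance(o, Tensor) else np.asarray(o) for o in outputs]
        n_img = raw[0].shape[0]
        na = len(anchor_pairs_per_level[0])
        results: list[list[Detection]] = []
        for img in range(n_img):
            cand_boxes, cand_scores, cand_cls = [], [], []
            for level, (stride, arr) in enumerate(zip(STRIDES, raw)):
                _, ch, h, w = arr.shape
                nc = ch // na - 5
                p = arr[img].reshape(na, 5 + nc, h, w)
                obj = _sigmoid(p[:, 4])
                cls = _sigmoid(p[:, 5:])                      # (na, nc, h, w)
                score = obj[:, None] * cls                    # joint confidence
                a_idx, c_idx, gy, gx = np.where(score > conf_thresh)
                if len(a_idx) == 0:
                    continue
                anchors = np.asarray(anchor_pairs_per_level[level], dtype=float)
                txy = _sigmoid(p[a_idx, 0:2, gy, gx]) * 2.0 - 0.5
                twh = (_sigmoid(p[a_idx, 2:4, gy, gx]) * 2.0) ** 2
                cx = (txy[:, 0] + gx) * stride
                cy = (txy[:, 1] + gy) * stride
                wh = twh * anchors[a_idx]
                cand_boxes.append(np.stack([cx, cy, wh[:, 0], wh[:, 1]], axis=1))
                cand_scores.append(score[a_idx, c_idx, gy, gx])
                cand_cls.append(c_idx)
            dets: list[Detection] = []
            if cand_boxes:
                boxes_arr = np.concatenate(cand_boxes)
                scores = np.concatenate(cand_scores)
                classes = np.concatenate(cand_cls)
                image_id = image_ids[img] if image_ids is not None else str(img)
                for c in np.unique(classes):
                    sel = classes == c
                    keep = _nms(boxes_arr[sel], scores[sel], nms_iou)
                    for k in keep[:max_det]:
                        b = boxes_arr[sel][k]
                        dets.append(Detection(
                            image_id=image_id,
                            box=Box(float(b[0]), float(b[1]),
                                    float(max(b[2], 1e-7)), float(max(b[3], 1e-7))),
                            score=float(scores[sel][k]),
                            class_id=int(c),
                        ))
                dets.sort(key=lambda d: -d.score)
            results.append(dets)
        return results


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
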