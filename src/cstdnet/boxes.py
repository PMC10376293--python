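"""Axis-aligned box geometry and bounding-box regression losses.

Boxes live in continuous pixel coordinates in center-size form
``(cx, cy, w, h)``.  The overlap family implemented here is the standard
IoU ladder used for box regression:

* ``iou``  — intersection over union;
* ``giou`` — IoU minus the normalized empty area of the smallest enclosing
  box (penalizes non-overlap);
* ``diou`` — IoU minus the squared center distance over the squared
  enclosing-box diagonal;
* ``ciou`` — DIoU minus an aspect-ratio consistency term ``alpha * v``;
* ``wh_ciou`` — a width/height-decoupled variant of CIoU: instead of the
  single aspect-ratio term it penalizes the width ratio ``w_pr / w_gt`` and
  the height ratio ``h_pr / h_gt`` separately, so the penalty does not
  vanish when the two aspect ratios merely agree.

CIoU and WH-CIoU are asymmetric in (prediction, ground truth); the other
three are symmetric.  All functions are vectorized over leading dimensions
and accept either :class:`Box` instances or ``(..., 4)`` center-form arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

#: dimensions below this are clamped by the geometric ops
GEOM_EPS = 1e-7
#: probability clamp for log terms in the cross entropy
PROB_EPS = 1e-7


class IoUVariant(str, Enum):
    IOU = "iou"
    GIOU = "giou"
    DIOU = "diou"
    CIOU = "ciou"
    WH_CIOU = "wh_ciou"


class EpsCombine(str, Enum):
    """How the width and height penalty terms of WH-CIoU are combined.

    ``PLUS`` sums the two squared deviations (the default: a nonnegative
    penalty that is zero only when both ratios are 1).  ``AS_PRINTED_MINUS``
    subtracts the height term from the width term, which can go negative;
    it is retained behind this flag so both readings of the formula are
    available, and neither is silently rewritten.
    """

    PLUS = "plus"
    AS_PRINTED_MINUS = "as_printed_minus"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, center-size form, pixels."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box dimensions must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @classmethod
    def from_corners(cls, x1, y1, x2, y2) -> "Box":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def to_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=float)


@dataclass
class OverlapResult:
    """The full overlap family for one pair (or an array of pairs)."""

    iou: np.ndarray
    giou: np.ndarray
    diou: np.ndarray
    ciou: np.ndarray
    wh_ciou: np.ndarray
    enclosure_area: np.ndarray
    center_dist_sq: np.ndarray
    diag_sq: np.ndarray


@dataclass
class LossConfig:
    """Weights and variant selection for the composite detection loss.

    ``total = w_conf * L_conf + w_cls * L_cls + w_loc * L_loc`` with the
    localization term ``1 - <variant>``.
    """

    w_conf: float = 0.1
    w_cls: float = 0.125
    w_loc: float = 0.05
    iou_variant: IoUVariant = IoUVariant.WH_CIOU
    bce_sample_weight: float = 1.0
    eps_combine: EpsCombine = EpsCombine.PLUS

    def __post_init__(self):
        self.iou_variant = IoUVariant(self.iou_variant)
        self.eps_combine = EpsCombine(self.eps_combine)
        if min(self.w_conf, self.w_cls, self.w_loc) < 0:
            raise ValueError("loss weights must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "w_conf": self.w_conf, "w_cls": self.w_cls, "w_loc": self.w_loc,
            "iou_variant": self.iou_variant.value,
            "bce_sample_weight": self.bce_sample_weight,
            "eps_combine": self.eps_combine.value,
        }


def _as_cxcywh(b) -> np.ndarray:
    if isinstance(b, Box):
        return b.to_array()
    arr = np.asarray(b, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError("expected (..., 4) center-form boxes")
    return arr


def _geometry(a, b, clamp=True):
    """Common corner/enclosure arithmetic for a pair of box arrays."""
    a, b = _as_cxcywh(a), _as_cxcywh(b)
    if clamp:
        a = a.copy()
        b = b.copy()
        a[..., 2:] = np.maximum(a[..., 2:], GEOM_EPS)
        b[..., 2:] = np.maximum(b[..., 2:], GEOM_EPS)
    ax1, ay1 = a[..., 0] - a[..., 2] / 2, a[..., 1] - a[..., 3] / 2
    ax2, ay2 = a[..., 0] + a[..., 2] / 2, a[..., 1] + a[..., 3] / 2
    bx1, by1 = b[..., 0] - b[..., 2] / 2, b[..., 1] - b[..., 3] / 2
    bx2, by2 = b[..., 0] + b[..., 2] / 2, b[..., 1] + b[..., 3] / 2
    iw = np.clip(np.minimum(ax2, bx2) - np.maximum(ax1, bx1), 0, None)
    ih = np.clip(np.minimum(ay2, by2) - np.maximum(ay1, by1), 0, None)
    inter = iw * ih
    area_a = a[..., 2] * a[..., 3]
    area_b = b[..., 2] * b[..., 3]
    union = area_a + area_b - inter
    cw = np.maximum(ax2, bx2) - np.minimum(ax1, bx1)
    ch = np.maximum(ay2, by2) - np.minimum(ay1, by1)
    enclosure = cw * ch
    diag_sq = cw * cw + ch * ch
    center_dist_sq = (a[..., 0] - b[..., 0]) ** 2 + (a[..., 1] - b[..., 1]) ** 2
    return a, b, inter, union, enclosure, center_dist_sq, diag_sq


def iou(a, b) -> np.ndarray:
    _, _, inter, union, *_ = _geometry(a, b)
    return inter / union


def giou(a, b) -> np.ndarray:
    _, _, inter, union, enclosure, _, _ = _geometry(a, b)
    return inter / union - (enclosure - union) / enclosure


def diou(a, b) -> np.ndarray:
    _, _, inter, union, _, rho2, d2 = _geometry(a, b)
    return inter / union - rho2 / d2


def _ciou_v(pr, gt) -> np.ndarray:
    """Aspect-ratio consistency term of CIoU."""
    return (4.0 / np.pi**2) * (
        np.arctan(gt[..., 2] / gt[..., 3]) - np.arctan(pr[..., 2] / pr[..., 3])
    ) ** 2


def ciou(pr, gt) -> np.ndarray:
    """CIoU of a prediction against a ground truth (asymmetric)."""
    pr_, gt_, inter, union, _, rho2, d2 = _geometry(pr, gt)
    i = inter / union
    v = _ciou_v(pr_, gt_)
    with np.errstate(invalid="ignore"):
        alpha = np.where(v > 0, v / ((1.0 - i) + v), 0.0)
    return i - rho2 / d2 - alpha * v


def wh_ciou_epsilon(pr, gt, eps_combine: EpsCombine = EpsCombine.PLUS) -> np.ndarray:
    """Width/height-ratio penalty: ``(2/pi^2)[(atan wr - pi/4)^2 (+/-) (atan hr - pi/4)^2]``."""
    pr, gt = _as_cxcywh(pr), _as_cxcywh(gt)
    wr = np.arctan(pr[..., 2] / gt[..., 2]) - np.pi / 4
    hr = np.arctan(pr[..., 3] / gt[..., 3]) - np.pi / 4
    if EpsCombine(eps_combine) is EpsCombine.PLUS:
        return (2.0 / np.pi**2) * (wr**2 + hr**2)
    return (2.0 / np.pi**2) * (wr**2 - hr**2)


def wh_ciou(pr, gt, cfg: LossConfig | None = None) -> np.ndarray:
    """WH-CIoU of a prediction against a ground truth (asymmetric).

    Raises if any ground-truth dimension is nonpositive: the ratios
    ``w_pr / w_gt`` and ``h_pr / h_gt`` are undefined there.
    """
    cfg = cfg or LossConfig()
    gt_arr = _as_cxcywh(gt)
    if np.any(gt_arr[..., 2:] <= 0):
        raise ValueError("ground-truth boxes must have positive width and height")
    pr_, gt_, inter, union, _, rho2, d2 = _geometry(pr, gt)
    i = inter / union
    eps = wh_ciou_epsilon(pr_, gt_, cfg.eps_combine)
    denom = (1.0 - i) + eps
    # beta * eps is defined as 0 exactly at eps = 0 (continuity); the tiny
    # guard keeps the as-printed variant finite when eps approaches IoU - 1.
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_eps = np.where(eps != 0, eps * eps / np.where(np.abs(denom) < 1e-12, 1e-12, denom), 0.0)
    return i - rho2 / d2 - beta_eps


_VARIANTS = {
    IoUVariant.IOU: iou,
    IoUVariant.GIOU: giou,
    IoUVariant.DIOU: diou,
    IoUVariant.CIOU: ciou,
}


def overlap(pr, gt, eps_combine: EpsCombine = EpsCombine.PLUS) -> OverlapResult:
    """Compute the whole overlap family at once (prediction first)."""
    pr_, gt_, inter, union, enclosure, rho2, d2 = _geometry(pr, gt)
    i = inter / union
    cfg = LossConfig(eps_combine=eps_combine)
    return OverlapResult(
        iou=i,
        giou=i - (enclosure - union) / enclosure,
        diou=i - rho2 / d2,
        ciou=ciou(pr, gt),
        wh_ciou=wh_ciou(pr, gt, cfg),
        enclosure_area=enclosure,
        center_dist_sq=rho2,
        diag_sq=d2,
    )


def localization_loss(pr, gt, cfg: LossConfig | None = None) -> np.ndarray:
    """``1 - <selected overlap variant>`` (nonnegative for plain IoU)."""
    cfg = cfg or LossConfig()
    if cfg.iou_variant is IoUVariant.WH_CIOU:
        return 1.0 - wh_ciou(pr, gt, cfg)
    return 1.0 - _VARIANTS[cfg.iou_variant](pr, gt)


def bce(target, pred, weight: float = 1.0) -> float:
    """Mean weighted binary cross entropy on probabilities.

    ``-(w/N) * sum(gt * ln(pr) + (1-gt) * ln(1-pr))`` with predictions
    clamped away from {0, 1} before the logs.
    """
    target = np.asarray(target, dtype=float)
    pred = np.clip(np.asarray(pred, dtype=float), PROB_EPS, 1.0 - PROB_EPS)
    terms = target * np.log(pred) + (1.0 - target) * np.log(1.0 - pred)
    return float(-weight * np.mean(terms))


def total_loss(l_conf: float, l_cls: float, l_loc: float,
               cfg: LossConfig | None = None) -> float:
    """Weighted sum of the three loss components."""
    cfg = cfg or LossConfig()
    return cfg.w_conf * l_conf + cfg.w_cls * l_cls + cfg.w_loc * l_loc
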