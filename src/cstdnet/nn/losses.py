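"""Differentiable overlap losses on autograd tensors.

The plain-numpy implementations in :mod:`cstdnet.boxes` are the reference;
this module re-expresses the same formulas with tape-recorded ops so the
localization loss can be backpropagated through the box decode during
training.  Following the usual CIoU convention, the trade-off weights
(``alpha`` for CIoU, ``beta`` for the width/height variant) are treated as
constants with respect to the gradient.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_GEOM_EPS = 1e-7


def _split(b):
    return b[..., 0], b[..., 1], ag.maximum(b[..., 2], _GEOM_EPS), ag.maximum(b[..., 3], _GEOM_EPS)


def iou_family(pr: Tensor, gt, variant: str = "wh_ciou",
               eps_combine: str = "plus") -> Tensor:
    """Selected overlap value for (..., 4) center-form box tensors."""
    if not isinstance(gt, Tensor):
        gt = Tensor(np.asarray(gt, dtype=pr.data.dtype))
    px, py, pw, ph = _split(pr)
    gx, gy, gw, gh = _split(gt)
    ax1, ay1 = px - pw * 0.5, py - ph * 0.5
    ax2, ay2 = px + pw * 0.5, py + ph * 0.5
    bx1, by1 = gx - gw * 0.5, gy - gh * 0.5
    bx2, by2 = gx + gw * 0.5, gy + gh * 0.5
    iw = ag.clip(ag.minimum(ax2, bx2) - ag.maximum(ax1, bx1), 0, None)
    ih = ag.clip(ag.minimum(ay2, by2) - ag.maximum(ay1, by1), 0, None)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    i = inter / union
    if variant == "iou":
        return i
    cw = ag.maximum(ax2, bx2) - ag.minimum(ax1, bx1)
    ch = ag.maximum(ay2, by2) - ag.minimum(ay1, by1)
    if variant == "giou":
        enc = cw * ch
        return i - (enc - union) / enc
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    d2 = cw * cw + ch * ch
    if variant == "diou":
        return i - rho2 / d2
    if variant == "ciou":
        v = ag.mul((ag.arctan(gw / gh) - ag.arctan(pw / ph)) ** 2, 4.0 / np.pi**2)
        alpha = v.data / ((1.0 - i.data) + v.data + 1e-9)
        return i - rho2 / d2 - ag.mul(v, alpha)
    if variant == "wh_ciou":
        wr = ag.arctan(pw / gw) - np.pi / 4
        hr = ag.arctan(ph / gh) - np.pi / 4
        if eps_combine == "plus":
            eps = ag.mul(wr**2 + hr**2, 2.0 / np.pi**2)
        else:
            eps = ag.mul(wr**2 - hr**2, 2.0 / np.pi**2)
        beta = eps.data / ((1.0 - i.data) + eps.data + 1e-9)
        return i - rho2 / d2 - ag.mul(eps, beta)
    raise ValueError(f"unknown overlap variant {variant!r}")


def localization_loss(pr: Tensor, gt, variant: str = "wh_ciou",
                      eps_combine: str = "plus") -> Tensor:
    """Mean ``1 - overlap`` over all box pairs."""
    return ag.tmean(1.0 - iou_family(pr, gt, variant, eps_combine))
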