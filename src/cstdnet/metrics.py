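"""Detection evaluation: matching, precision/recall/F1 and average precision.

Matching follows the VOC convention: detections are visited in descending
score order (ties broken by detection index) and each is matched greedily
to the best not-yet-matched ground truth of its image; a detection counts
as a true positive iff that best IoU reaches the matching threshold
(default 0.7 here).  AP is the all-point-interpolated area under the
precision-recall curve obtained by sweeping the score-ranked detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boxes import Box, iou as box_iou

DEFAULT_IOU_THRESH = 0.7
DEFAULT_CONF_THRESH = 0.5


@dataclass(frozen=True)
class Detection:
    """A scored predicted box, referenced to an image."""

    image_id: str
    box: Box
    score: float
    class_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    det_is_tp: np.ndarray  # aligned with score-sorted detection order
    det_order: np.ndarray  # indices into the input detection list


@dataclass
class PRCurve:
    """Cumulative precision/recall along the score-ranked detection sweep."""

    recall: np.ndarray
    precision: np.ndarray
    tp_cum: np.ndarray
    fp_cum: np.ndarray
    n_gt: int
    scores: np.ndarray = None  # score at each sweep position (descending)

    def __post_init__(self):
        if len(self.recall) and np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing along the sweep")


def _group_gts(gts) -> dict[str, np.ndarray]:
    """Normalize ground truths to image_id -> (n, 4) center-form array."""
    if not isinstance(gts, dict):
        raise TypeError("gts must be a mapping image_id -> boxes")
    out = {}
    for k, v in gts.items():
        arrs = [b.to_array() if isinstance(b, Box) else np.asarray(b, dtype=float)
                for b in v]
        out[k] = np.stack(arrs) if arrs else np.zeros((0, 4))
    return out


def _sorted_dets(dets: list[Detection]):
    order = np.lexsort((np.arange(len(dets)), -np.array([d.score for d in dets])))
    return order


def match(dets: list[Detection], gts, iou_thresh: float = DEFAULT_IOU_THRESH) -> MatchResult:
    """Greedy one-to-one matching of detections against ground truths."""
    gt_map = _group_gts(gts)
    n_gt = sum(len(v) for v in gt_map.values())
    order = _sorted_dets(dets)
    matched: dict[str, np.ndarray] = {k: np.zeros(len(v), dtype=bool) for k, v in gt_map.items()}
    is_tp = np.zeros(len(dets), dtype=bool)
    for rank, idx in enumerate(order):
        d = dets[idx]
        g = gt_map.get(d.image_id)
        if g is None or not len(g):
            continue
        free = ~matched[d.image_id]
        if not free.any():
            continue
        cand = np.where(free)[0]
        ious = box_iou(np.broadcast_to(d.box.to_array(), (len(cand), 4)), g[cand])
        best = int(np.argmax(ious))
        if ious[best] >= iou_thresh:
            matched[d.image_id][cand[best]] = True
            is_tp[rank] = True
    tp = int(is_tp.sum())
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=n_gt - tp,
                       det_is_tp=is_tp, det_order=order)


def precision(tp: int, fp: int) -> float:
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    return tp / (tp + fn) if tp + fn else 0.0


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return 2.0 * p * r / (p + r) if p + r else 0.0


def pr_curve(dets: list[Detection], gts, iou_thresh: float = DEFAULT_IOU_THRESH) -> PRCurve:
    gt_map = _group_gts(gts)
    n_gt = sum(len(v) for v in gt_map.values())
    m = match(dets, gts, iou_thresh)
    tp_cum = np.cumsum(m.det_is_tp.astype(float))
    fp_cum = np.cumsum((~m.det_is_tp).astype(float))
    rec = tp_cum / n_gt if n_gt else np.zeros_like(tp_cum)
    prec = np.where(tp_cum + fp_cum > 0, tp_cum / (tp_cum + fp_cum), 0.0)
    scores = np.array([dets[i].score for i in m.det_order], dtype=float)
    return PRCurve(recall=rec, precision=prec, tp_cum=tp_cum, fp_cum=fp_cum,
                   n_gt=n_gt, scores=scores)


def average_precision(dets: list[Detection], gts,
                      iou_thresh: float = DEFAULT_IOU_THRESH) -> float:
    """All-point interpolated area under the precision-recall curve.

    Equal-score detections enter the sweep together (the curve is sampled
    only where the score strictly drops), so the result does not depend on
    the ordering of ties.
    """
    curve = pr_curve(dets, gts, iou_thresh)
    if curve.n_gt == 0 or len(curve.recall) == 0:
        return 0.0
    # keep only the last sweep position of each distinct score
    last = np.ones(len(curve.scores), dtype=bool)
    last[:-1] = np.diff(curve.scores) != 0
    # precision envelope: best precision achievable at recall >= r
    rec = np.concatenate([[0.0], curve.recall[last], [curve.recall[-1]]])
    prec = np.concatenate([[0.0], curve.precision[last], [0.0]])
    prec = np.maximum.accumulate(prec[::-1])[::-1]
    steps = np.where(np.diff(rec) > 0)[0]
    return float(np.sum((rec[steps + 1] - rec[steps]) * prec[steps + 1]))


def summarize(dets: list[Detection], gts, iou_thresh: float = DEFAULT_IOU_THRESH,
              conf_thresh: float = DEFAULT_CONF_THRESH) -> dict[str, float]:
    """P/R/F1 at a confidence cutoff plus threshold-free AP."""
    cut = [d for d in dets if d.score >= conf_thresh]
    m = match(cut, gts, iou_thresh)
    p, r = precision(m.tp, m.fp), recall(m.tp, m.fn)
    return {"P": p, "R": r, "F1": f1(p, r),
            "AP": average_precision(dets, gts, iou_thresh)}


def metric_table(model_results: dict[str, tuple[list[Detection], dict]],
                 iou_thresh: float = DEFAULT_IOU_THRESH,
                 conf_thresh: float = DEFAULT_CONF_THRESH) -> pd.DataFrame:
    """One row of P/R/F1/AP per model (mirrors the comparison-table layout)."""
    rows = []
    for name, (dets, gts) in model_results.items():
        rows.append({"model": name, **summarize(dets, gts, iou_thresh, conf_thresh)})
    return pd.DataFrame(rows).set_index("model")


def write_metric_csv(table: pd.DataFrame, path) -> None:
    table.round(4).to_csv(path)


def read_metric_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
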