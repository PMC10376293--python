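"""Anchor priors, IoU-distance k-means clustering and training-target assignment.

Anchors are (w, h) pixel templates, nine per model, grouped three per
detection scale with the smallest group on stride 8.  The default set is
tuned for small faces (8-55 px sides, most edges between 24 and 32 px);
the stock YOLOv7 set is kept alongside for comparison runs.

Target assignment is the YOLOv5-style ratio gate: a ground truth is
assigned to an anchor at a level iff max(w/aw, aw/w, h/ah, ah/h) is below a
threshold (4.0), at the grid cell containing its center plus the two
nearest neighbor cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRIDES = (8, 16, 32)
RATIO_THRESHOLD = 4.0
NEIGHBOR_BIAS = 0.5


@dataclass(frozen=True)
class AnchorSet:
    """Nine (w, h) anchor pairs grouped 3-per-scale across strides 8/16/32."""

    pairs: tuple

    def __post_init__(self):
        arr = np.asarray(self.pairs, dtype=float)
        if arr.shape != (9, 2):
            raise ValueError("an AnchorSet holds exactly 9 (w, h) pairs")
        if np.any(arr <= 0):
            raise ValueError("anchor dimensions must be positive")
        areas = arr.prod(axis=1).reshape(3, 3).mean(axis=1)
        if np.any(np.diff(areas) <= 0):
            raise ValueError("anchor groups must have increasing mean area "
                             "(smallest group on stride 8)")
        object.__setattr__(self, "pairs", tuple(map(tuple, arr)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pairs, dtype=float)

    @property
    def per_scale(self) -> dict[int, np.ndarray]:
        arr = self.as_array()
        return {s: arr[3 * i: 3 * i + 3] for i, s in enumerate(STRIDES)}

    def to_list(self) -> list[list[float]]:
        return [list(p) for p in self.pairs]


def default_small_target_anchors() -> AnchorSet:
    """The anchor set tuned for 8-55 px faces."""
    return AnchorSet((
        (5, 9), (12, 16), (19, 36),
        (42, 31), (40, 28), (55, 48),
        (36, 75), (76, 55), (72, 146),
    ))


def yolov7_default_anchors() -> AnchorSet:
    """The stock YOLOv7 anchor set (for comparison baselines)."""
    return AnchorSet((
        (12, 16), (19, 36), (40, 28),
        (36, 75), (76, 55), (72, 146),
        (142, 110), (192, 243), (459, 401),
    ))


def _iou_wh(pairs_a: np.ndarray, pairs_b: np.ndarray) -> np.ndarray:
    """IoU of (w, h) rectangles anchored at a common origin; (n, m) matrix."""
    a = pairs_a[:, None, :]
    b = pairs_b[None, :, :]
    inter = np.minimum(a[..., 0], b[..., 0]) * np.minimum(a[..., 1], b[..., 1])
    union = a[..., 0] * a[..., 1] + b[..., 0] * b[..., 1] - inter
    return inter / union


def kmeans_anchors(boxes, k: int, seed: int = 0, iters: int = 300,
                   return_history: bool = False):
    """k-means under the 1 - IoU distance with k-means++ seeding.

    ``boxes`` is an (n, 2) array (or list) of (w, h) pairs.  Returns the
    (k, 2) centroid array sorted by area; with ``return_history`` also the
    per-iteration mean-distance objective (non-increasing).
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    if boxes.shape[0] < k:
        raise ValueError(f"need at least k={k} boxes, got {boxes.shape[0]}")
    rng = np.random.default_rng(seed)
    # k-means++ seeding under the same distance
    centroids = [boxes[rng.integers(len(boxes))]]
    for _ in range(1, k):
        d = 1.0 - _iou_wh(boxes, np.asarray(centroids)).max(axis=1)
        probs = d / d.sum() if d.sum() > 0 else np.full(len(boxes), 1.0 / len(boxes))
        centroids.append(boxes[rng.choice(len(boxes), p=probs)])
    centroids = np.asarray(centroids, dtype=float)
    history = []
    assign = None
    prev_centroids = centroids.copy()
    for _ in range(iters):
        dist = 1.0 - _iou_wh(boxes, centroids)
        new_assign = dist.argmin(axis=1)
        objective = float(dist[np.arange(len(boxes)), new_assign].mean())
        # the mean update is a heuristic under the IoU distance: stop (and
        # revert) the moment a step fails to improve the objective
        if history and objective > history[-1] + 1e-12:
            centroids = prev_centroids
            break
        history.append(objective)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        prev_centroids = centroids.copy()
        for j in range(k):
            members = boxes[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:  # dead centroid: reseed at the farthest box
                far = dist.min(axis=1).argmax()
                centroids[j] = boxes[far]
    centroids = centroids[np.argsort(centroids.prod(axis=1))]
    return (centroids, np.asarray(history)) if return_history else centroids


def anchor_set_from_boxes(boxes, seed: int = 0) -> AnchorSet:
    """Cluster nine anchors from training boxes and group them by scale.

    Tiny datasets (< 9 boxes) are padded with multiplicatively jittered
    copies so nine distinct clusters exist.
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    if len(boxes) < 27:
        rng = np.random.default_rng(seed)
        reps = int(np.ceil(27 / len(boxes)))
        jitter = rng.uniform(0.7, 1.4, size=(reps * len(boxes), 2))
        boxes = np.tile(boxes, (reps, 1)) * jitter
    cents = kmeans_anchors(boxes, 9, seed=seed)
    # enforce strictly increasing group areas (degenerate ties get a nudge)
    areas = cents.prod(axis=1)
    for i in range(1, 9):
        if areas[i] <= areas[i - 1]:
            cents[i] *= np.sqrt(areas[i - 1] * 1.02 / areas[i])
            areas = cents.prod(axis=1)
    return AnchorSet(tuple(map(tuple, cents)))


def box_size_summary(boxes) -> tuple[float, float, tuple[int, int]]:
    """(min side, max side, modal 8-px side bin) over (w, h) pairs.

    The modal range is the most populated 8-px-wide bin of the pooled
    side-length histogram, reported as a half-open interval [lo, hi).
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    sides = boxes.ravel()
    min_side = float(sides.min())
    max_side = float(boxes.max(axis=1).max())
    bins = (sides // 8).astype(int)
    modal = np.bincount(bins).argmax()
    return min_side, max_side, (int(modal * 8), int(modal * 8 + 8))


@dataclass
class AssignedTargets:
    """Positive training samples for one pyramid level.

    Arrays are aligned: sample ``i`` is (image ``img[i]``, anchor slot
    ``anchor[i]``, grid cell ``(gj[i], gi[i])`` as row/col) regressing
    ground-truth box ``box[i]`` (center form, pixels) of class ``cls[i]``.
    """

    stride: int
    img: np.ndarray
    anchor: np.ndarray
    gj: np.ndarray
    gi: np.ndarray
    box: np.ndarray
    cls: np.ndarray

    def __len__(self):
        return len(self.img)


def assign_targets(gt_boxes_per_image, anchors: AnchorSet, input_size: int,
                   classes_per_image=None,
                   ratio_thresh: float = RATIO_THRESHOLD) -> dict[int, AssignedTargets]:
    """Build positive samples per level for a batch of images.

    ``gt_boxes_per_image`` is a sequence (one entry per image) of (n, 4)
    center-form pixel boxes.  Boxes with centers outside the image are
    rejected with a warning.  Returns a mapping stride -> targets.
    """
    import warnings

    per_scale = anchors.per_scale
    out: dict[int, AssignedTargets] = {}
    for stride in STRIDES:
        grid = input_size // stride
        lvl_anchors = per_scale[stride]
        imgs, ancs, gjs, gis, bxs, cls_out = [], [], [], [], [], []
        for img_idx, boxes in enumerate(gt_boxes_per_image):
            boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
            if boxes.size == 0:
                continue
            classes = (np.zeros(len(boxes), dtype=int)
                       if classes_per_image is None
                       else np.asarray(classes_per_image[img_idx], dtype=int))
            for b_idx, b in enumerate(boxes):
                cx, cy, w, h = b
                if not (0 <= cx <= input_size and 0 <= cy <= input_size):
                    warnings.warn(f"ground truth center outside image: {b}")
                    continue
                gx, gy = cx / stride, cy / stride
                for a_idx, (aw, ah) in enumerate(lvl_anchors):
                    r = max(w / aw, aw / w, h / ah, ah / h)
                    if r >= ratio_thresh:
                        continue
                    ci, cj = int(gx), int(gy)
                    cells = {(min(cj, grid - 1), min(ci, grid - 1))}
                    fx, fy = gx - ci, gy - cj
                    if fx < NEIGHBOR_BIAS and ci > 0:
                        cells.add((min(cj, grid - 1), ci - 1))
                    elif fx >= NEIGHBOR_BIAS and ci < grid - 1:
                        cells.add((min(cj, grid - 1), ci + 1))
                    if fy < NEIGHBOR_BIAS and cj > 0:
                        cells.add((cj - 1, min(ci, grid - 1)))
                    elif fy >= NEIGHBOR_BIAS and cj < grid - 1:
                        cells.add((cj + 1, min(ci, grid - 1)))
                    for gj, gi in sorted(cells):
                        imgs.append(img_idx)
                        ancs.append(a_idx)
                        gjs.append(gj)
                        gis.append(gi)
                        bxs.append(b)
                        cls_out.append(classes[b_idx])
        out[stride] = AssignedTargets(
            stride=stride,
            img=np.asarray(imgs, dtype=int),
            anchor=np.asarray(ancs, dtype=int),
            gj=np.asarray(gjs, dtype=int),
            gi=np.asarray(gis, dtype=int),
            box=np.asarray(bxs, dtype=float).reshape(-1, 4),
            cls=np.asarray(cls_out, dtype=int),
        )
    return out
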