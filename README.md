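# cstdnet

Detection of **small faces in livestock imagery** — the setting where goat
faces captured by pasture cameras occupy only 8–55 pixels of a 1920×1080
frame, cluster tightly, and sit in cluttered, variably lit backgrounds.
`cstdnet` implements a contextual small-target detection network and the
full experimental harness around it: box-regression losses, anchor
clustering and assignment, Pascal VOC data tooling, Mosaic/Mixup
augmentation, a synthetic scene generator, detection metrics, and
rank-based model-comparison statistics.

## What is implemented

**Network.** A one-stage anchor-based detector: CSP-style backbone tapped at
strides 8/16/32, SPPCSPC on the deepest tap, and a neck built from two
ideas aimed at small targets —

* **CIDM** (context information detection module): four parallel 3×3
  dilated convolutions (rates 1–4) extract multi-scale local context
  `F₂ = CAT(Conv(k=3, p=i, r=i)(F₂)), i = 1..4`, while the adjacent pyramid
  levels are resampled, gated by efficient channel attention, convolved,
  and summed in: `F = F₁ + F₂ + F₃`.
* **FCM** (feature complementary module): adjacent levels are fused by
  elementwise products of cross-resampled features
  (`f₁₂ = Conv(down(f₁))·Conv(f₂)`, `f₂₁ = Conv(up(f₂))·Conv(f₁)`, then
  `Conv(f₂₁)·Conv(up(f₁₂))` for the up path and `Conv(f₁₂)·Conv(down(f₂₁))`
  for the down path), and the two paths are compared by an absolute
  difference `|F_A − F_B|` that cancels background response shared by both.

Three YOLO-style heads emit `anchors × (4 + 1 + classes)` channels — 18 for
the single-class model — on 80×80 / 40×40 / 20×20 maps at 640-pixel input.

**WH-CIoU loss.** CIoU's aspect-ratio term vanishes whenever the predicted
and true aspect ratios merely agree. The width/height-decoupled variant
penalizes the two size ratios separately:

    WH-CIoU = IoU − ρ²(p_pr, p_gt)/d² − β·ε,
    ε = (2/π²)[(arctan(w_pr/w_gt) − π/4)² + (arctan(h_pr/h_gt) − π/4)²],
    β = ε / ((1 − IoU) + ε)

with the composite objective `Loss = 0.1·L_conf + 0.125·L_cls + 0.05·L_loc`
and `L_loc = 1 − {IoU | GIoU | DIoU | CIoU | WH-CIoU}`.

**Statistics.** Friedman's rank test over models × metrics plus the Nemenyi
post-hoc critical distance `CD = q_α(k)·√(k(k+1)/6n)`, with the published
comparison tables packaged as CSV fixtures.

The whole stack — including a compact reverse-mode autodiff engine over
numpy (`cstdnet.nn`) that powers the network — runs on a single CPU, so
every component is testable at desk scale.

## Worked example

```python
from cstdnet import Box, iou, wh_ciou
from cstdnet.stats import compare_report, load_table, rank_table_from_frame

gt = Box(cx=30, cy=30, w=12, h=18)
pr = Box(cx=33, cy=28, w=24, h=18)       # doubled width, small offset
print(f"IoU     = {iou(pr, gt):.4f}")
print(f"WH-CIoU = {wh_ciou(pr, gt):.4f}")

rt = rank_table_from_frame(load_table("small_target_ranks"))
report = compare_report(rt, alpha=0.05)
print(f"chi2 = {report.chi2:.3f}, p = {report.p_value:.3f}, "
      f"CD = {report.critical_distance:.3f}")
print("significant:", report.significant_pairs())
```

prints

```
IoU     = 0.4211
WH-CIoU = 0.4070
chi2 = 14.429, p = 0.013, CD = 3.770
significant: [('SSD', 'Ours'), ('YOLOV5', 'Ours')]
```

The WH-CIoU value sits below plain IoU because the doubled predicted width
and the center offset are both penalized. The Friedman statistic over the
six-model rank table rejects model equality (p = 0.013 < 0.05), and the
Nemenyi test flags the full model as significantly better than the two
weakest baselines — pairs whose average-rank gap exceeds the critical
distance 3.770.

A command-line interface mirrors the library:

```bash
cstdnet synth --n 16 --seed 0 --out data/scenes           # synthetic dataset
cstdnet train --config cfg.yaml --out runs/exp1           # training
cstdnet evaluate --ckpt runs/exp1/checkpoint_epoch0100.npz \
                 --data data/scenes/manifest.txt --iou 0.7 --conf 0.5
cstdnet predict --ckpt ... --images frame.png
cstdnet compare --csv results.csv --alpha 0.05            # Friedman/Nemenyi
```

## Scope notes

The real goat-face video corpus is not publicly deposited, so the data
pipeline ships a seed-deterministic synthetic scene generator emulating its
regime (many 8–55 px textured faces, cluster placement, daylight
illumination sweep, sensor noise); absolute detection scores on the real
data are out of scope. See `docs/methods.md` for the model assumptions,
parameter choices and limitations.
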