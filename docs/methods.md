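# Methods

## Problem setting

Pasture cameras record goat herds at 1920×1080; individual faces span
roughly 8–55 pixels, with most box edges between 24 and 32 pixels, often
clustered, under lighting that varies across the day. A face is treated as
a *small target* when its longer box side is at most 50 px; dataset
construction keeps an image only if **every** face in it satisfies this
(a box-level filtering mode is available as well; the boundary value 50
itself survives the filter).

## Model

The detector is a one-stage anchor-based network with three output scales
(strides 8, 16, 32).

* **Backbone** — a compact CSP-style stem + three downsampling stages with
  cross-stage-partial bodies. Tap channels are `4b / 8b / 16b` for
  `base_channels = b` (default 16). The backbone is deliberately generic:
  the contribution of the architecture lies in the neck, and any backbone
  honoring the three-scale stride/channel contract can stand in.
* **SPPCSPC** — spatial pyramid pooling (max pools 5/9/13, stride 1) inside
  a channel split on the deepest tap; enlarges the receptive field without
  changing resolution.
* **CIDM** — per level, four parallel 3×3 dilated convolutions with rates
  (and paddings) 1–4, each emitting C/4 channels, concatenated back to C;
  the coarser neighbor is bilinearly upsampled and the finer neighbor
  average-pooled, each gated by ECA channel attention and convolved to C
  channels; the present branches are summed. At pyramid ends the absent
  neighbor's branch is simply omitted (the "CIDM1" variant). The C/4
  branch split is the minimal choice that makes the concatenation and the
  elementwise sum shape-legal.
* **FCM** — the three neck levels are channel-aligned by dilated
  convolutions with kernels 3/5/7 (rate 2, padding k−1; the rate is a
  design choice, chosen once, since only the kernel sizes are prescribed by
  the construction). Adjacent pairs are fused by elementwise products of
  cross-resampled features; each pair's up-path and down-path outputs are
  compared by an absolute difference at the pair's finer resolution; the
  two difference maps are resampled to the block's target stride,
  concatenated (2C channels) and reduced by a 1×1 convolution. `up()` is
  bilinear interpolation and `down()` 2×2 average pooling throughout,
  including inside CIDM. The exact pairing/difference wiring inside the
  block is under-determined by the construction's prose; the wiring above
  is this package's documented choice, fixed by the stride contract.
* **Heads** — bare 1×1 convolutions emitting `na·(4+1+nc)` channels. The
  objectness bias is initialized to −5 so early confidence is low.
  Decoding follows the YOLOv5 convention (`2σ−0.5` cell offsets,
  `(2σ)²·anchor` sizes) with per-class greedy NMS.

All convolution blocks are conv + batch norm + SiLU unless an equation
names a bare convolution. Weights are Kaiming-normal, batch-norm γ=1 β=0;
a single integer seed fixes the full initialization.

### Numerical engine

The network runs on a small reverse-mode autodiff core over numpy
(`cstdnet.nn.autograd`): tape-recorded elementwise ops, reductions,
indexing, im2col convolution, max/average pooling, bilinear resampling and
batch normalization. Every op's gradient is verified against central
finite differences in the test suite. Float32 is used for weights and
activations; the engine is dtype-preserving so the gradient checks run in
float64.

## Anchors and assignment

Nine (w, h) anchors, grouped three per scale with the smallest group on
stride 8. The small-target default is
(5,9) (12,16) (19,36) / (42,31) (40,28) (55,48) / (36,75) (76,55) (72,146);
the stock YOLOv7 set is retained for baselines. `kmeans_anchors` clusters
box shapes under the 1−IoU distance (boxes at a common origin) with
k-means++ seeding; because the arithmetic-mean centroid update is a
heuristic under this distance, iteration stops (and reverts) the moment the
objective fails to improve, which guarantees a non-increasing objective
trace. Datasets with fewer than 27 boxes are padded with multiplicatively
jittered copies before clustering.

Training-target assignment is the YOLOv5-style ratio gate: an anchor is
positive for a ground truth iff `max(w/aw, aw/w, h/ah, ah/h) < 4`, at the
center cell plus up to two nearest neighbor cells (offset bias 0.5). The
full OTA-style dynamic assignment of newer YOLO variants is intentionally
out of scope: the quantities of interest here are the anchors and the loss,
and the ratio gate is standard and exactly testable (the suite checks it
against exhaustive enumeration).

## Losses

`Loss = 0.1·L_conf + 0.125·L_cls + 0.05·L_loc`. Confidence and class terms
are binary cross entropy (a global sample weight ω multiplies both;
ω defaults to 1 as no other value is prescribed); probabilities are clamped
to [1e−7, 1−1e−7] before logs, and the training path uses the logit-space
formulation for stability.

The localization term is `1 − v` for the selected overlap variant
`v ∈ {IoU, GIoU, DIoU, CIoU, WH-CIoU}`. Conventions:

* `d²` is the squared diagonal of the smallest box enclosing the pair
  (standard DIoU convention).
* CIoU's `α·v` and WH-CIoU's `β·ε` are defined as exactly 0 when the
  consistency term is 0 (continuity at the degenerate point).
* The WH-CIoU penalty combines the width and height deviations as a **sum**
  by default (`eps_combine="plus"`), which keeps the penalty nonnegative
  and zero only at exact size agreement. A printed form that subtracts the
  height term from the width term — allowing negative ε — is retained
  behind `eps_combine="as_printed_minus"`; both behaviors are unit-tested
  and neither is silently rewritten. Because
  `arctan(1/x) − π/4 = −(arctan x − π/4)`, the squared penalties are
  invariant under swapping prediction and truth; the asymmetry of the
  formula lives in its role contract (ground-truth sides must be strictly
  positive, predicted sides are epsilon-clamped at 1e−7 px).
* Geometric ops clamp box sides at 1e−7 px; loss-side ground truths with
  nonpositive sides raise.

In the training graph the trade-off weights α and β are treated as
constants with respect to the gradient, the usual CIoU convention.

## Data pipeline

Pascal VOC 2007 XML with 1-based inclusive corners maps to internal
continuous half-open corner form (`xmin−1, ymin−1, xmax, ymax`), an exact
round trip for integer corners. Mosaic stitches four randomly rescaled
images around a random center; boxes are clipped per quadrant and dropped
below 8 px² (a documented constant that avoids degenerate slivers). Mixup
blends two images as `λ·a + (1−λ)·b`, unites the label sets, and carries λ
and 1−λ as per-box weights; λ ~ Beta(8, 8) when unspecified. Video frame
extraction is out of scope — the generator emits stills directly.

### Synthetic scenes

The generator renders a low-frequency grass/dirt texture, places two-tone
elliptical "faces" (darker forehead band, two eye dots, mild pelt noise)
with sides uniform in the configured range and height/width ratio in
[1.0, 1.5], optionally clustered (default probability 0.5, Gaussian scatter
around an existing face), applies a global illumination factor (default
range 0.55–1.05, emulating the 6:00–18:00 capture window) and additive
Gaussian sensor noise (default sd 4 on the 8-bit scale), and emits exact
boxes. Defaults are 1920×1080 frames with 3–12 faces of side 8–55 px,
matching the scale regime of the real footage. Everything is driven by one
`numpy` Generator, so scenes are bit-identical per seed.

What the generator does **not** emulate: real pelt texture and pose
variation, occlusion between animals, motion blur, compression artifacts,
and background objects that resemble faces. Passing tests therefore
demonstrate that the implementation is correct and trainable on data of the
right scale statistics — not that the reported real-data accuracy
transfers.

## Evaluation

Greedy score-descending one-to-one matching (ties broken by detection
index); a detection is a true positive iff its best unmatched ground truth
reaches the IoU threshold (default 0.7). P/R/F1 are reported at a
confidence cutoff (default 0.5 — the original protocol does not state one,
so this is documented, not asserted as the authors'); AP is the
all-point-interpolated area under the precision–recall sweep, with
equal-score detections entering the sweep together so tie order cannot
change the result.

## Model comparison

Models are ranked per metric (rank 1 best, ties averaged). The classical
Friedman statistic is used on tie-free tables; with ties the Conover
chi-square form applies (it reduces to the classical one without ties).
p-values come from the χ²(k−1) reference distribution. Nemenyi critical
values q(α, k) for k = 2..10 at α ∈ {0.05, 0.10} are embedded (infinite-df
studentized range over √2) and cross-checked against
`scipy.stats.studentized_range` in the tests.

## Training protocol

Defaults: batch 8, AdamW, initial learning rate 1e−4 held constant (no
schedule is prescribed), 100 epochs with a checkpoint every 10 — the
"every 10 of 100 iterations" cadence is read at epoch granularity, the only
reading consistent with a multi-thousand-image training set. Checkpoints
are self-describing `.npz` archives (weights, batch-norm statistics, model
+ loss + anchor config), so evaluation and prediction need no external
config. With a fixed seed and single-threaded math the loop is
deterministic.

### Desk-scale configuration

The test suite's end-to-end check trains on eight 64×64 synthetic scenes
holding 1–2 faces of side 10–24 px, with a `base_channels = 8` model at
input 64, k-means anchors from the training boxes, AdamW at 5e−3 (a tiny
model memorizing eight images supports a larger constant step than the
full-scale default), no augmentation, 300 epochs. These sizes are the
package's chosen desk-scale study conditions: large enough for the network
to express its three-scale structure, small enough that the whole suite
runs on one CPU in about a minute. The check asserts ≥ 90% reduction of
the composite loss from epoch 1 and AP@0.5 ≥ 0.9 on the training split.

## Known limitations

* The backbone is a compact stand-in honoring the three-scale contract,
  not a re-parameterized E-ELAN graph; absolute accuracy at full scale is
  not a goal of this implementation.
* Sample assignment is the static ratio gate, not OTA.
* The numpy engine is single-device and unbatched across processes;
  training beyond desk scale is out of scope.
* The Friedman statistic printed for the normal-size comparison in the
  source tables (18.813) is not reproducible from the printed ranks under
  either the classical (18.25) or tie-corrected (18.381) form, and the
  printed P-column ranks of that table are internally inconsistent with
  the corresponding metric table; that table ships as printed and is not
  used as a numeric target.
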