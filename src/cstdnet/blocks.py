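"""Building blocks of the contextual small-target detection network.

The neck is built from three ideas:

* **CIDM** (context information detection module): multi-rate dilated
  convolutions extract local context at the current pyramid level, while the
  two adjacent levels are resampled, gated by efficient channel attention
  (ECA) and added in — so a small face is seen together with its
  surroundings.  At pyramid ends the missing neighbor branch is simply
  omitted (the "CIDM1" variant).
* **FCM** (feature complementary module): pairs of adjacent levels are fused
  by elementwise products of cross-resampled features, and the up-path and
  down-path fusions are compared by an absolute difference, which cancels
  background response shared by both paths.
* **SPPCSPC**: spatial pyramid pooling inside a cross-stage-partial split,
  enlarging the receptive field of the deepest level at constant resolution.

Every convolution block is conv + batch norm + SiLU unless noted; all
blocks preserve their declared (stride, channels) contract.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, autograd as ag
from .nn.modules import ConvBNSiLU, Module, Sequential


def adaptive_eca_kernel(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Nearest odd kernel size from the channel count (standard ECA rule)."""
    t = int(abs((np.log2(channels) + b) / gamma))
    return t if t % 2 else t + 1


class ECA(Module):
    """Efficient channel attention: sigmoid gate from a 1-D convolution
    over the globally average-pooled channel descriptor."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel: int | str = "adaptive"):
        super().__init__()
        k = adaptive_eca_kernel(channels) if kernel == "adaptive" else int(kernel)
        if k % 2 == 0:
            raise ValueError("ECA kernel must be odd")
        self.k = k
        w = rng.standard_normal((1, 1, k, 1)) * np.sqrt(2.0 / k)
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        desc = ag.tmean(x, axis=(2, 3))                       # (N, C)
        desc = ag.reshape(desc, (n, 1, c, 1))
        gate = ag.conv2d(desc, self.weight, padding=(self.k // 2, 0))
        gate = ag.sigmoid(ag.reshape(gate, (n, c, 1, 1)))
        return x * gate


class LocalContext(Module):
    """Four parallel 3x3 dilated convolutions (rates 1..4, padding = rate),
    each emitting C/4 channels, concatenated back to C channels."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 4:
            raise ValueError("local context requires channels divisible by 4")
        for i in range(1, 5):
            setattr(self, f"branch{i}",
                    ConvBNSiLU(channels, channels // 4, 3, rng,
                               dilation=i, padding=i))

    def forward(self, x):
        return ag.concatenate(
            [self.branch1(x), self.branch2(x), self.branch3(x), self.branch4(x)],
            axis=1,
        )

    @staticmethod
    def receptive_field(rate: int, kernel: int = 3) -> int:
        """Effective receptive field of one dilated branch."""
        return kernel + (kernel - 1) * (rate - 1)


class CIDM(Module):
    """Context information detection module.

    Branch B extracts multi-rate local context at the current level; branch
    A brings in the coarser neighbor (bilinear 2x upsample, ECA, conv) and
    branch C the finer one (2x2 average pool, ECA, conv).  The present
    branches are summed elementwise.  Instantiating with a missing neighbor
    gives the pyramid-end variant.
    """

    def __init__(self, c_cur: int, rng: np.random.Generator,
                 c_coarse: int | None = None, c_fine: int | None = None,
                 eca_kernel: int | str = "adaptive"):
        super().__init__()
        self.local = LocalContext(c_cur, rng)
        self.has_coarse = c_coarse is not None
        self.has_fine = c_fine is not None
        if self.has_coarse:
            self.eca_coarse = ECA(c_coarse, rng, eca_kernel)
            self.conv_coarse = ConvBNSiLU(c_coarse, c_cur, 3, rng)
        if self.has_fine:
            self.eca_fine = ECA(c_fine, rng, eca_kernel)
            self.conv_fine = ConvBNSiLU(c_fine, c_cur, 3, rng)

    def forward(self, f_cur, f_coarse=None, f_fine=None):
        if self.has_coarse != (f_coarse is not None) or self.has_fine != (f_fine is not None):
            raise ValueError("CIDM called with neighbors it was not built for")
        out = self.local(f_cur)
        if self.has_coarse:
            out = out + self.conv_coarse(self.eca_coarse(ag.upsample_bilinear2x(f_coarse)))
        if self.has_fine:
            out = out + self.conv_fine(self.eca_fine(ag.avg_pool2d(f_fine)))
        return out


def difference(fa, fb):
    """Elementwise absolute difference of two same-shaped feature maps."""
    if fa.shape != fb.shape:
        raise ValueError("difference requires identical feature specs")
    return ag.tabs(fa - fb)


class FCMPair(Module):
    """Cross-resolution complementary fusion of one adjacent-level pair.

    With ``f1`` the finer and ``f2`` the coarser (2x stride) input:

    * ``f12 = Conv(down(f1)) * Conv(f2)`` at the coarse resolution,
    * ``f21 = Conv(up(f2)) * Conv(f1)`` at the fine resolution,
    * up path:   ``Conv(f21) * Conv(up(f12))`` at the fine resolution,
    * down path: ``Conv(f12) * Conv(down(f21))`` at the coarse resolution.

    ``up`` is bilinear interpolation, ``down`` is 2x2 average pooling.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        for name in ("conv_down_f1", "conv_f2", "conv_up_f2", "conv_f1",
                     "conv_f21", "conv_up_f12", "conv_f12", "conv_down_f21"):
            setattr(self, name, ConvBNSiLU(channels, channels, 3, rng))

    def _intermediates(self, f1, f2):
        f12 = self.conv_down_f1(ag.avg_pool2d(f1)) * self.conv_f2(f2)
        f21 = self.conv_up_f2(ag.upsample_bilinear2x(f2)) * self.conv_f1(f1)
        return f12, f21

    def up(self, f1, f2):
        f12, f21 = self._intermediates(f1, f2)
        return self.conv_f21(f21) * self.conv_up_f12(ag.upsample_bilinear2x(f12))

    def down(self, f1, f2):
        f12, f21 = self._intermediates(f1, f2)
        return self.conv_f12(f12) * self.conv_down_f21(ag.avg_pool2d(f21))

    def forward(self, f1, f2):
        f12, f21 = self._intermediates(f1, f2)
        up_out = self.conv_f21(f21) * self.conv_up_f12(ag.upsample_bilinear2x(f12))
        down_out = self.conv_f12(f12) * self.conv_down_f21(ag.avg_pool2d(f21))
        return up_out, down_out


class FCMBlock(Module):
    """Three-level feature complementary block.

    The three inputs (finest to coarsest) are channel-aligned by dilated
    convolutions with kernels 3, 5 and 7 (rate 2), the two adjacent pairs
    are fused by :class:`FCMPair`, each pair's up-path and down-path outputs
    are compared by an absolute difference at the pair's finer resolution,
    and the two difference maps are resampled to the block's target stride,
    concatenated and reduced by a 1x1 convolution.
    """

    def __init__(self, c_in: tuple[int, int, int], c_align: int, c_out: int,
                 direction: str, rng: np.random.Generator):
        super().__init__()
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        self.direction = direction
        self.align1 = ConvBNSiLU(c_in[0], c_align, 3, rng, dilation=2, padding=2)
        self.align2 = ConvBNSiLU(c_in[1], c_align, 5, rng, dilation=2, padding=4)
        self.align3 = ConvBNSiLU(c_in[2], c_align, 7, rng, dilation=2, padding=6)
        self.pair12 = FCMPair(c_align, rng)
        self.pair23 = FCMPair(c_align, rng)
        self.reduce = ConvBNSiLU(2 * c_align, c_out, 1, rng)

    def forward(self, x1, x2, x3):
        a1, a2, a3 = self.align1(x1), self.align2(x2), self.align3(x3)
        up12, down12 = self.pair12(a1, a2)
        up23, down23 = self.pair23(a2, a3)
        # compare at each pair's finer resolution
        d1 = difference(up12, ag.upsample_bilinear2x(down12))      # stride of x1
        d2 = difference(up23, ag.upsample_bilinear2x(down23))      # stride of x2
        if self.direction == "up":
            d2 = ag.upsample_bilinear2x(d2)
        else:
            d1 = ag.avg_pool2d(ag.avg_pool2d(d1))
            d2 = ag.avg_pool2d(d2)
        return self.reduce(ag.concatenate([d1, d2], axis=1))


class SPPCSPC(Module):
    """Spatial pyramid pooling inside a cross-stage-partial split.

    One half of the (projected) features passes through parallel max pools
    with kernels 5/9/13 at stride 1; the other half bypasses; the merged
    result keeps the spatial size.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        c_ = max(c_out // 2, 4)
        self.cv_main = ConvBNSiLU(c_in, c_, 1, rng)
        self.cv_pre = ConvBNSiLU(c_, c_, 3, rng)
        self.cv_post = ConvBNSiLU(4 * c_, c_, 1, rng)
        self.cv_bypass = ConvBNSiLU(c_in, c_, 1, rng)
        self.cv_out = ConvBNSiLU(2 * c_, c_out, 1, rng)

    def forward(self, x):
        y = self.cv_pre(self.cv_main(x))
        pools = [ag.max_pool2d(y, k, stride=1, padding=k // 2) for k in (5, 9, 13)]
        y = self.cv_post(ag.concatenate([y] + pools, axis=1))
        return self.cv_out(ag.concatenate([y, self.cv_bypass(x)], axis=1))


class CSPStage(Module):
    """Stride-2 downsampling stage with a cross-stage-partial body."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        c_ = c_out // 2
        self.down = ConvBNSiLU(c_in, c_out, 3, rng, stride=2)
        self.cv1 = ConvBNSiLU(c_out, c_, 1, rng)
        self.cv2 = ConvBNSiLU(c_out, c_, 1, rng)
        self.body = Sequential(
            ConvBNSiLU(c_, c_, 3, rng),
            ConvBNSiLU(c_, c_, 3, rng),
        )
        self.merge = ConvBNSiLU(c_out, c_out, 1, rng)

    def forward(self, x):
        y = self.down(x)
        return self.merge(ag.concatenate([self.cv1(y), self.body(self.cv2(y))], axis=1))


class Backbone(Module):
    """Compact CSP-style backbone with taps at strides 8, 16 and 32."""

    def __init__(self, base_channels: int, rng: np.random.Generator):
        super().__init__()
        b = base_channels
        self.stem = ConvBNSiLU(3, b, 3, rng, stride=2)
        self.down2 = ConvBNSiLU(b, 2 * b, 3, rng, stride=2)
        self.stage3 = CSPStage(2 * b, 4 * b, rng)
        self.stage4 = CSPStage(4 * b, 8 * b, rng)
        self.stage5 = CSPStage(8 * b, 16 * b, rng)
        self.tap_channels = (4 * b, 8 * b, 16 * b)

    def forward(self, x):
        x = self.down2(self.stem(x))
        p3 = self.stage3(x)
        p4 = self.stage4(p3)
        p5 = self.stage5(p4)
        return p3, p4, p5
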