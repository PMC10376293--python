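"""Shape contracts and arithmetic traces of the network blocks."""

import numpy as np
import pytest

from cstdnet import blocks as blk
from cstdnet.model import CSTDNet, FeatureMapSpec, ModelConfig, decode_predictions
from cstdnet.nn import Tensor, autograd as ag
from cstdnet.nn.modules import Module


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


def rand_map(rng, c, h, w, n=1):
    return t(rng.standard_normal((n, c, h, w)))


@pytest.fixture
def mrng():
    return np.random.default_rng(0)


class TestECA:
    def test_shape_preserved(self, mrng, rng):
        eca = blk.ECA(16, mrng)
        x = rand_map(rng, 16, 8, 8)
        assert eca(x).shape == x.shape

    def test_zero_input_stays_zero(self, mrng):
        eca = blk.ECA(16, mrng)
        x = t(np.zeros((1, 16, 4, 4)))
        assert np.all(eca(x).data == 0)

    def test_channel_constant_input_scaled_into_unit_interval(self, mrng):
        eca = blk.ECA(8, mrng)
        x = t(np.ones((1, 8, 4, 4)))
        y = eca(x).data
        scale = y / x.data
        assert np.all(scale > 0) and np.all(scale < 1)
        # gate constant per channel
        assert np.allclose(scale, scale[:, :, :1, :1])

    def test_even_kernel_rejected(self, mrng):
        with pytest.raises(ValueError):
            blk.ECA(8, mrng, kernel=4)


class TestLocalContext:
    def test_channel_count_preserved(self, mrng, rng):
        lc = blk.LocalContext(64, mrng)
        x = rand_map(rng, 64, 10, 10)
        assert lc(x).shape == (1, 64, 10, 10)

    def test_indivisible_channels_rejected(self, mrng):
        with pytest.raises(ValueError):
            blk.LocalContext(6, mrng)

    def test_receptive_field_of_dilated_branches(self):
        # RF = k + (k-1)(r-1) for a single dilated conv
        assert blk.LocalContext.receptive_field(1) == 3
        assert blk.LocalContext.receptive_field(4) == 9


class TestCIDM:
    def test_full_module_preserves_current_spec(self, mrng, rng):
        m = blk.CIDM(16, mrng, c_coarse=32, c_fine=8)
        out = m(rand_map(rng, 16, 8, 8), f_coarse=rand_map(rng, 32, 4, 4),
                f_fine=rand_map(rng, 8, 16, 16))
        assert out.shape == (1, 16, 8, 8)

    def test_pyramid_end_variant_omits_missing_branch(self, mrng, rng):
        m = blk.CIDM(16, mrng, c_coarse=None, c_fine=8)
        out = m(rand_map(rng, 16, 8, 8), f_fine=rand_map(rng, 8, 16, 16))
        assert out.shape == (1, 16, 8, 8)
        with pytest.raises(ValueError):
            m(rand_map(rng, 16, 8, 8))  # built with a fine branch: must get one

    def test_zeroed_neighbor_convs_leave_only_local_context(self, mrng, rng):
        m = blk.CIDM(16, mrng, c_coarse=32, c_fine=8)
        for conv in (m.conv_coarse, m.conv_fine):
            conv.conv.weight.data[...] = 0.0
        cur = rand_map(rng, 16, 8, 8)
        out = m(cur, f_coarse=rand_map(rng, 32, 4, 4), f_fine=rand_map(rng, 8, 16, 16))
        assert np.allclose(out.data, m.local(cur).data, atol=1e-6)


class Identity(Module):
    def forward(self, x):
        return x


class TestFCM:
    def test_pair_output_resolutions(self, mrng, rng):
        pair = blk.FCMPair(8, mrng)
        up, down = pair(rand_map(rng, 8, 8, 8), rand_map(rng, 8, 4, 4))
        assert up.shape == (1, 8, 8, 8)
        assert down.shape == (1, 8, 4, 4)

    def test_zero_inputs_give_zero_products(self, mrng):
        pair = blk.FCMPair(8, mrng)
        up, down = pair(t(np.zeros((1, 8, 8, 8))), t(np.zeros((1, 8, 4, 4))))
        assert np.all(up.data == 0) and np.all(down.data == 0)

    def test_identity_conv_scalar_trace(self, mrng):
        """With all convs replaced by identities the chain reduces to
        products of the two constants: both paths yield (a*b)^2."""
        pair = blk.FCMPair(1, mrng)
        for name in ("conv_down_f1", "conv_f2", "conv_up_f2", "conv_f1",
                     "conv_f21", "conv_up_f12", "conv_f12", "conv_down_f21"):
            setattr(pair, name, Identity())
        a, b = 3.0, 5.0
        f1 = t(np.full((1, 1, 2, 2), a))
        f2 = t(np.full((1, 1, 1, 1), b))
        up, down = pair(f1, f2)
        assert np.allclose(up.data, (a * b) ** 2)
        assert np.allclose(down.data, (a * b) ** 2)

    def test_difference_properties(self, rng):
        fa = rand_map(rng, 4, 6, 6)
        fb = rand_map(rng, 4, 6, 6)
        d = blk.difference(fa, fb)
        assert np.all(d.data >= 0)
        assert np.allclose(d.data, blk.difference(fb, fa).data)
        assert np.all(blk.difference(fa, fa).data == 0)
        const = blk.difference(t(np.full((1, 2, 3, 3), 3.0)), t(np.full((1, 2, 3, 3), 5.0)))
        assert np.allclose(const.data, 2.0)
        with pytest.raises(ValueError):
            blk.difference(fa, rand_map(rng, 4, 3, 3))

    def test_block_target_strides_and_concat_width(self, mrng, rng):
        x1, x2, x3 = (rand_map(rng, 8, 16, 16), rand_map(rng, 16, 8, 8),
                      rand_map(rng, 32, 4, 4))
        up_block = blk.FCMBlock((8, 16, 32), 8, 8, "up", mrng)
        down_block = blk.FCMBlock((8, 16, 32), 8, 32, "down", mrng)
        assert up_block(x1, x2, x3).shape == (1, 8, 16, 16)
        assert down_block(x1, x2, x3).shape == (1, 32, 4, 4)
        # the reduction conv consumes the concat of the two difference maps
        assert up_block.reduce.conv.weight.shape[1] == 2 * 8

    def test_zero_inputs_give_zero_block_output(self, mrng):
        block = blk.FCMBlock((8, 8, 8), 8, 8, "up", mrng)
        out = block(t(np.zeros((1, 8, 8, 8))), t(np.zeros((1, 8, 4, 4))),
                    t(np.zeros((1, 8, 2, 2))))
        assert np.allclose(out.data, 0.0, atol=1e-6)


class TestSPPCSPC:
    def test_spatial_size_preserved(self, mrng, rng):
        spp = blk.SPPCSPC(32, 32, mrng)
        assert spp(rand_map(rng, 32, 5, 5)).shape == (1, 32, 5, 5)

    def test_max_pool_is_identity_on_constant_maps(self, rng):
        x = t(np.full((1, 4, 6, 6), 2.5))
        for k in (5, 9, 13):
            assert np.allclose(ag.max_pool2d(x, k, 1, k // 2).data, 2.5)

    def test_deterministic_for_fixed_seed(self, rng):
        x = rand_map(rng, 32, 5, 5)
        a = blk.SPPCSPC(32, 32, np.random.default_rng(3))(x)
        b = blk.SPPCSPC(32, 32, np.random.default_rng(3))(x)
        assert np.array_equal(a.data, b.data)


class TestModelAssembly:
    def test_head_channel_arithmetic(self):
        cfg = ModelConfig(input_size=640, num_classes=1, anchors_per_scale=3)
        assert cfg.head_channels == 18

    @pytest.mark.parametrize("size,expect", [(640, [80, 40, 20]), (416, [52, 26, 13])])
    def test_head_spec_sizes(self, size, expect):
        cfg = ModelConfig(input_size=640)
        specs = cfg.head_specs(size)
        assert [s.height for s in specs] == sorted(expect, reverse=True)
        assert all(s.channels == 18 for s in specs)

    def test_forward_shapes_at_96(self, rng):
        model = CSTDNet(ModelConfig(input_size=96, base_channels=8), seed=0)
        outs = model(rng.standard_normal((1, 3, 96, 96)).astype(np.float32))
        assert [o.shape for o in outs] == [(1, 18, 12, 12), (1, 18, 6, 6), (1, 18, 3, 3)]

    def test_indivisible_input_rejected(self):
        model = CSTDNet(ModelConfig(input_size=64, base_channels=8), seed=0)
        with pytest.raises(ValueError):
            model(np.zeros((1, 3, 60, 60), dtype=np.float32))
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)

    def test_forward_is_finite_over_many_random_inputs(self):
        model = CSTDNet(ModelConfig(input_size=32, base_channels=8), seed=0)
        model.eval()
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal((1, 3, 32, 32)).astype(np.float32)
            outs = model(x)
            assert all(np.isfinite(o.data).all() for o in outs)

    def test_parameter_count_deterministic(self):
        a = CSTDNet(ModelConfig(input_size=64, base_channels=8), seed=0)
        b = CSTDNet(ModelConfig(input_size=64, base_channels=8), seed=99)
        assert a.num_parameters() == b.num_parameters()

    def test_feature_map_spec_validation(self):
        with pytest.raises(ValueError):
            FeatureMapSpec(stride=7, channels=8, height=4, width=4)


class TestDecode:
    def _anchors(self):
        return [np.array([[8.0, 8.0], [12, 12], [16, 16]])] * 3

    def test_cold_logits_yield_no_detections(self):
        outs = [np.full((1, 18, s, s), -40.0) for s in (8, 4, 2)]
        dets = decode_predictions(outs, self._anchors(), conf_thresh=0.25)
        assert dets == [[]]

    def test_single_hot_cell_decodes_to_expected_location(self):
        outs = [np.full((1, 18, s, s), -40.0) for s in (8, 4, 2)]
        # anchor slot 1 at cell (row 2, col 3) on stride 8, zero offsets
        lvl = outs[0].reshape(1, 3, 6, 8, 8)
        lvl[0, 1, 0, 2, 3] = 0.0   # tx: sigmoid 0.5 -> offset 0.5
        lvl[0, 1, 1, 2, 3] = 0.0
        lvl[0, 1, 2, 2, 3] = 0.0   # tw: (2*0.5)^2 = 1 -> anchor size
        lvl[0, 1, 3, 2, 3] = 0.0
        lvl[0, 1, 4, 2, 3] = 8.0   # objectness
        lvl[0, 1, 5, 2, 3] = 8.0   # class
        dets = decode_predictions(outs, self._anchors(), conf_thresh=0.25)[0]
        assert len(dets) == 1
        d = dets[0]
        assert d.box.cx == pytest.approx((0.5 + 3) * 8)
        assert d.box.cy == pytest.approx((0.5 + 2) * 8)
        assert d.box.w == pytest.approx(12.0)
        assert d.box.h == pytest.approx(12.0)

    def test_nms_keeps_highest_scoring_duplicate(self):
        outs = [np.full((1, 18, s, s), -40.0) for s in (8, 4, 2)]
        lvl = outs[0].reshape(1, 3, 6, 8, 8)
        for slot, obj in ((0, 2.2), (1, 1.4)):   # same cell, overlapping boxes
            lvl[0, slot, 0:4, 4, 4] = 0.0
            lvl[0, slot, 4, 4, 4] = obj
            lvl[0, slot, 5, 4, 4] = 8.0
        anchors = [np.array([[12.0, 12.0], [12.5, 12.5], [16, 16]])] * 3
        dets = decode_predictions(outs, anchors, conf_thresh=0.25, nms_iou=0.5)[0]
        assert len(dets) == 1
        assert dets[0].score == pytest.approx(1 / (1 + np.exp(-2.2)) * (1 / (1 + np.exp(-8))), rel=1e-6)
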