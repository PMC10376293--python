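"""Box geometry and regression-loss behavior.

The independent oracles here are (a) pixel-grid rasterization for IoU on
integer-corner boxes, (b) direct corner arithmetic re-derived from scratch
for the distance/enclosure quantities, and (c) literal scalar evaluation of
the penalty formulas.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cstdnet import boxes as B
from cstdnet.nn import SGD, Tensor
from cstdnet.nn.losses import iou_family, localization_loss as loc_loss_t

from conftest import random_box


def raster_iou(a_corners, b_corners, size=80):
    """Count-overlap oracle on the integer pixel grid (exact for integer corners)."""
    grid_a = np.zeros((size, size), dtype=bool)
    grid_b = np.zeros((size, size), dtype=bool)
    x1, y1, x2, y2 = map(int, a_corners)
    grid_a[y1:y2, x1:x2] = True
    x1, y1, x2, y2 = map(int, b_corners)
    grid_b[y1:y2, x1:x2] = True
    inter = (grid_a & grid_b).sum()
    union = (grid_a | grid_b).sum()
    return inter / union if union else 0.0


class TestIoUFamily:
    def test_identical_boxes_score_one_in_every_variant(self):
        b = B.Box(10, 12, 4, 6)
        res = B.overlap(b, b)
        for name in ("iou", "giou", "diou", "ciou", "wh_ciou"):
            assert getattr(res, name) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_boxes_have_zero_iou(self):
        a, b = B.Box(5, 5, 4, 4), B.Box(50, 50, 4, 4)
        assert B.iou(a, b) == 0.0

    def test_overlapping_unit_squares(self):
        a = B.Box.from_corners(0, 0, 2, 2)
        b = B.Box.from_corners(1, 1, 3, 3)
        assert B.iou(a, b) == pytest.approx(1 / 7, abs=1e-12)

    def test_giou_of_separated_squares(self):
        a = B.Box.from_corners(0, 0, 1, 1)
        b = B.Box.from_corners(2, 0, 3, 1)
        assert B.giou(a, b) == pytest.approx(-1 / 3, abs=1e-12)

    def test_concentric_boxes_make_diou_equal_iou(self):
        a, b = B.Box(10, 10, 4, 4), B.Box(10, 10, 8, 2)
        assert B.diou(a, b) == pytest.approx(B.iou(a, b), abs=1e-12)

    def test_equal_aspect_ratio_degrades_ciou_to_diou(self):
        pr, gt = B.Box(8, 9, 6, 3), B.Box(10, 10, 4, 2)
        assert B.ciou(pr, gt) == pytest.approx(B.diou(pr, gt), abs=1e-12)

    def test_ciou_aspect_penalty_matches_direct_formula(self):
        pr, gt = B.Box(10, 10, 2, 1), B.Box(10, 10, 1, 1)
        v = (4 / np.pi**2) * (np.arctan(1) - np.arctan(2)) ** 2
        alpha = v / ((1 - B.iou(pr, gt)) + v)
        assert B.ciou(pr, gt) == pytest.approx(B.diou(pr, gt) - alpha * v, abs=1e-12)

    def test_rasterization_oracle_on_random_integer_boxes(self, rng):
        for _ in range(200):
            x1, y1 = rng.integers(0, 56, 2)
            a = (x1, y1, x1 + rng.integers(1, 9), y1 + rng.integers(1, 9))
            x1, y1 = rng.integers(0, 56, 2)
            b = (x1, y1, x1 + rng.integers(1, 9), y1 + rng.integers(1, 9))
            got = B.iou(B.Box.from_corners(*a), B.Box.from_corners(*b))
            assert got == pytest.approx(raster_iou(a, b), abs=1e-6)

    def test_diou_matches_corner_arithmetic_oracle(self, rng):
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            # independent re-derivation from corners
            ac = np.array([a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2])
            bc = np.array([b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2])
            cw = max(ac[2], bc[2]) - min(ac[0], bc[0])
            ch = max(ac[3], bc[3]) - min(ac[1], bc[1])
            rho2 = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
            expect = B.iou(a, b) - rho2 / (cw**2 + ch**2)
            assert B.diou(a, b) == pytest.approx(expect, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_variant_ordering_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_box(r), random_box(r)
        res = B.overlap(a, b)
        assert 0.0 <= res.iou <= 1.0
        for name in ("giou", "diou", "ciou", "wh_ciou"):
            assert getattr(res, name) <= res.iou + 1e-9
        assert res.ciou <= res.diou + 1e-9
        for fn in (B.iou, B.giou, B.diou):
            assert fn(a, b) == pytest.approx(fn(b, a), abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_iou_invariant_under_shared_shift_and_scale(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_box(r), random_box(r)
        base = B.iou(a, b)
        shift = np.array([13.5, -7.25, 0, 0])
        assert B.iou(a + shift, b + shift) == pytest.approx(base, abs=1e-10)
        assert B.iou(a * 3.25, b * 3.25) == pytest.approx(base, abs=1e-10)


class TestWHCIoU:
    def test_perfect_prediction_scores_one(self):
        gt = B.Box(20, 20, 10, 14)
        assert B.wh_ciou(gt, gt) == pytest.approx(1.0, abs=1e-12)

    def test_matching_sizes_reduce_to_center_distance_penalty(self):
        gt = B.Box(20, 20, 10, 14)
        pr = B.Box(24, 17, 10, 14)
        assert B.wh_ciou(pr, gt) == pytest.approx(B.diou(pr, gt), abs=1e-12)

    def test_scalar_formula_oracle(self):
        """Literal evaluation of IoU - rho^2/d^2 - beta*eps for a doubled width."""
        gt = B.Box(20, 20, 8, 8)
        pr = B.Box(22, 20, 16, 8)
        i = B.iou(pr, gt)
        eps = (2 / np.pi**2) * (np.arctan(2) - np.pi / 4) ** 2
        beta = eps / ((1 - i) + eps)
        # enclosure of the pair, re-derived
        cw = max(22 + 8, 20 + 4) - min(22 - 8, 20 - 4)
        ch = 8.0
        expect = i - (2.0**2) / (cw**2 + ch**2) - beta * eps
        assert B.wh_ciou(pr, gt) == pytest.approx(expect, abs=1e-12)

    def test_as_printed_minus_combination(self):
        gt = B.Box(0, 0, 8, 8)
        pr = B.Box(0, 0, 16, 16)  # both ratios 2: the printed difference cancels
        eps_minus = B.wh_ciou_epsilon(pr.to_array(), gt.to_array(),
                                      B.EpsCombine.AS_PRINTED_MINUS)
        assert eps_minus == pytest.approx(0.0, abs=1e-12)
        eps_plus = B.wh_ciou_epsilon(pr.to_array(), gt.to_array(), B.EpsCombine.PLUS)
        assert eps_plus == pytest.approx((4 / np.pi**2) * (np.arctan(2) - np.pi / 4) ** 2)

    def test_roles_are_directional_only_ground_truth_dims_are_strict(self):
        """pr and gt play distinct roles: tiny predicted sides are clamped,
        while nonpositive ground-truth sides are a hard error."""
        ok = B.Box(0, 0, 8, 8).to_array()
        degenerate = ok.copy()
        degenerate[2] = 0.0
        assert np.isfinite(B.wh_ciou(degenerate, ok))
        with pytest.raises(ValueError):
            B.wh_ciou(ok, degenerate)

    def test_zero_sized_ground_truth_rejected(self):
        pr = B.Box(0, 0, 4, 4).to_array()
        gt = pr.copy()
        gt[2] = 0.0
        with pytest.raises(ValueError):
            B.wh_ciou(pr, gt)


class TestLosses:
    def test_localization_loss_zero_for_identical_boxes(self):
        b = B.Box(5, 5, 3, 3)
        for variant in B.IoUVariant:
            cfg = B.LossConfig(iou_variant=variant)
            assert B.localization_loss(b, b, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_localization_loss_one_for_disjoint_iou(self):
        cfg = B.LossConfig(iou_variant=B.IoUVariant.IOU)
        assert B.localization_loss(B.Box(0, 0, 2, 2), B.Box(50, 50, 2, 2), cfg) == 1.0

    def test_localization_loss_composes_with_wh_ciou(self, rng):
        a, b = random_box(rng), random_box(rng)
        cfg = B.LossConfig(iou_variant=B.IoUVariant.WH_CIOU)
        assert B.localization_loss(a, b, cfg) == pytest.approx(1.0 - B.wh_ciou(a, b, cfg))

    def test_bce_closed_forms(self):
        assert B.bce(1.0, 1.0 - 1e-9) == pytest.approx(0.0, abs=1e-6)
        assert B.bce(1.0, 0.5) == pytest.approx(np.log(2), abs=1e-9)
        assert B.bce(1.0, 0.5, weight=2.0) == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_total_loss_coefficients(self):
        assert B.total_loss(0, 0, 0) == 0.0
        assert B.total_loss(1, 0, 0) == pytest.approx(0.1)
        assert B.total_loss(0, 1, 0) == pytest.approx(0.125)
        assert B.total_loss(0, 0, 1) == pytest.approx(0.05)
        assert B.total_loss(1, 1, 1) == pytest.approx(0.275)


class TestDifferentiablePath:
    """The autograd loss re-expression must agree with the numpy reference."""

    @pytest.mark.parametrize("variant", ["iou", "giou", "diou", "ciou", "wh_ciou"])
    def test_tensor_overlap_matches_reference(self, variant, rng):
        pr = np.stack([random_box(rng) for _ in range(50)])
        gt = np.stack([random_box(rng) for _ in range(50)])
        got = iou_family(Tensor(pr), gt, variant=variant).data
        ref = {
            "iou": B.iou, "giou": B.giou, "diou": B.diou,
            "ciou": B.ciou, "wh_ciou": B.wh_ciou,
        }[variant](pr, gt)
        assert np.allclose(got, ref, atol=1e-6)

    def test_gradient_descent_on_wh_ciou_is_monotone(self):
        """500 fixed-step descent steps on one box shrink the loss monotonically."""
        gt = np.array([32.0, 32.0, 12.0, 18.0])
        pr = Tensor(np.array([20.0, 40.0, 20.0, 8.0]), requires_grad=True)
        opt = SGD([pr], lr=1.0)
        losses = []
        for _ in range(500):
            loss = loc_loss_t(pr.reshape(1, 4), gt.reshape(1, 4), variant="wh_ciou")
            losses.append(loss.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        losses = np.asarray(losses)
        assert np.all(np.diff(losses) <= 1e-9)
        assert losses[-1] < 0.25 * losses[0]
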