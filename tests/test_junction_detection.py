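import math

import numpy as np
import pytest

from retinareg.junction_detection import (
    ANCHORS_PER_CELL,
    AnchorSpec,
    DetectionBox,
    FeaturePyramid,
    JDN,
    JDNConfig,
    ResidualBlock,
    boxes_to_points,
    decode_detections,
    focal_loss,
    make_anchors,
    smooth_l1,
)
from retinareg.nn import Tensor


class TestAnchors:
    def test_unit_scale_unit_ratio(self):
        spec = AnchorSpec(base_sizes={3: 32.0})
        anchors = make_anchors(spec, 3, (1, 1))
        # first anchor: S = 2^0, AR = 1 -> H = W = 32
        assert anchors[0, 2] == pytest.approx(32.0)
        assert anchors[0, 3] == pytest.approx(32.0)

    def test_six_anchors_per_location(self):
        spec = AnchorSpec(base_sizes={4: 32.0})
        anchors = make_anchors(spec, 4, (3, 5))
        assert len(anchors) == 3 * 5 * 6

    def test_area_preserving_aspect_ratio(self):
        """At AR = 2 the area stays BA^2 while W/H = 2 (the reading with
        the radical: H = BA/sqrt(AR), W = BA*sqrt(AR))."""
        spec = AnchorSpec(base_sizes={3: 32.0})
        anchors = make_anchors(spec, 3, (1, 1))
        h, w = anchors[1, 2], anchors[1, 3]  # S = 2^0, AR = 2
        assert h * w == pytest.approx(32.0**2)
        assert w / h == pytest.approx(2.0)

    def test_total_count_matches_combinatorial_formula(self):
        cfg = JDNConfig()
        from retinareg.junction_detection import PYRAMID_LEVELS, _anchor_pack

        size = 256
        packs = _anchor_pack(cfg, size)
        total = sum(len(p) for p in packs.values())
        expected = sum((size // 2**lvl) ** 2 * 6 for lvl in PYRAMID_LEVELS)
        assert total == expected

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            make_anchors(AnchorSpec(base_sizes={3: 0.0}), 3, (1, 1))


class TestResidualBlock:
    def test_zero_residual_weights_give_relu_identity(self):
        rng = np.random.default_rng(0)
        blk = ResidualBlock(4, 4, rng=rng)
        blk.eval()
        blk.conv3.weight.data[:] = 0.0  # kill the residual branch output
        x = Tensor(rng.normal(0, 1, (1, 4, 8, 8)))
        out = blk(x)
        np.testing.assert_allclose(out.data, np.maximum(x.data, 0.0), atol=1e-6)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(1)
        blk = ResidualBlock(4, 8, rng=rng)
        blk.eval()
        out = blk(Tensor(rng.normal(0, 1, (1, 4, 8, 8))))
        assert out.data.min() >= 0.0

    def test_stride_two_halves_spatial_size(self):
        blk = ResidualBlock(4, 8, stride=2, rng=np.random.default_rng(0))
        blk.eval()
        out = blk(Tensor(np.random.default_rng(1).normal(0, 1, (1, 4, 16, 16))))
        assert out.data.shape == (1, 8, 8, 8)


class TestFeaturePyramid:
    def _pyramid(self):
        return FeaturePyramid(4, 8, 16, width=8, rng=np.random.default_rng(0))

    def test_level_sizes(self):
        fpn = self._pyramid()
        fpn.eval()
        rng = np.random.default_rng(1)
        out = fpn(
            Tensor(rng.normal(0, 1, (1, 4, 32, 32))),
            Tensor(rng.normal(0, 1, (1, 8, 16, 16))),
            Tensor(rng.normal(0, 1, (1, 16, 8, 8))),
        )
        assert [out[l].data.shape[-1] for l in (3, 4, 5, 6, 7)] == [32, 16, 8, 4, 2]

    def test_zero_inputs_zero_outputs_with_zero_biases(self):
        fpn = self._pyramid()
        fpn.eval()
        for mod in fpn.modules():
            if hasattr(mod, "bias") and mod.bias is not None:
                mod.bias.data[:] = 0.0
        out = fpn(
            Tensor(np.zeros((1, 4, 32, 32), np.float32)),
            Tensor(np.zeros((1, 8, 16, 16), np.float32)),
            Tensor(np.zeros((1, 16, 8, 8), np.float32)),
        )
        for lvl in (3, 4, 5, 6, 7):
            np.testing.assert_allclose(out[lvl].data, 0.0, atol=1e-7)

    def test_top_down_information_flow(self):
        """M4 (hence P4) must change when C5 is perturbed."""
        fpn = self._pyramid()
        fpn.eval()
        rng = np.random.default_rng(2)
        c3 = Tensor(rng.normal(0, 1, (1, 4, 32, 32)))
        c4 = Tensor(rng.normal(0, 1, (1, 8, 16, 16)))
        c5a = rng.normal(0, 1, (1, 16, 8, 8))
        a = fpn(c3, c4, Tensor(c5a))[4].data
        b = fpn(c3, c4, Tensor(c5a + 1.0))[4].data
        assert not np.allclose(a, b)

    def test_bad_size_ratio_rejected(self):
        fpn = self._pyramid()
        with pytest.raises(ValueError):
            fpn(
                Tensor(np.zeros((1, 4, 32, 32), np.float32)),
                Tensor(np.zeros((1, 8, 16, 16), np.float32)),
                Tensor(np.zeros((1, 16, 9, 9), np.float32)),
            )


class TestLosses:
    def test_perfect_prediction_vanishes(self):
        assert focal_loss(1 - 1e-12, 1) == pytest.approx(0.0, abs=1e-9)

    def test_gamma_zero_is_cross_entropy_closed_form(self):
        assert focal_loss(0.5, 1, gamma=0.0, alpha=1.0) == pytest.approx(math.log(2))

    def test_hand_evaluated_example(self):
        # gamma 2, alpha 0.25, p 0.9, y 1
        assert focal_loss(0.9, 1, 2.0, 0.25) == pytest.approx(
            -0.25 * 0.1**2 * math.log(0.9)
        )

    def test_gamma_zero_equals_cross_entropy_on_grid(self):
        for p in np.linspace(0.01, 0.99, 50):
            for y in (0, 1):
                ce = -math.log(p if y == 1 else 1 - p)
                assert abs(focal_loss(p, y, 0.0, 1.0) - ce) < 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            focal_loss(0.0, 1)

    @pytest.mark.parametrize("d,expected", [(0.0, 0.0), (1.0, 0.5), (2.0, 1.5), (-2.0, 1.5), (0.5, 0.125)])
    def test_smooth_l1_closed_form(self, d, expected):
        assert smooth_l1(d) == pytest.approx(expected)

    def test_smooth_l1_continuous_at_one(self):
        eps = 1e-9
        assert abs(smooth_l1(1 - eps) - smooth_l1(1 + eps)) < 1e-6


class TestDecoding:
    def _level(self, scores, boxes):
        return {3: scores}, {3: boxes}, {3: np.array([[16.0, 16.0, 8.0, 8.0]] * len(scores))}

    def test_nothing_above_threshold(self):
        sc = np.full((10, 1), 0.01)
        dl = np.zeros((10, 4))
        anchors = {3: np.tile([16.0, 16.0, 8.0, 8.0], (10, 1))}
        assert decode_detections({3: sc}, {3: dl}, anchors, 0.05, 0.3) == []

    def test_identical_boxes_collapse_to_one(self):
        n = 300
        sc = np.full((n, 1), 0.9)
        dl = np.zeros((n, 4))
        anchors = {3: np.tile([16.0, 16.0, 8.0, 8.0], (n, 1))}
        out = decode_detections({3: sc}, {3: dl}, anchors, 0.05, 0.3)
        assert len(out) == 1

    def test_cap_at_200_highest_scoring(self):
        """250 disjoint boxes above threshold: exactly the 200 best
        survive, in descending score order."""
        n = 250
        centers = np.arange(n) * 32.0 + 16.0
        anchors = {3: np.stack([centers, np.full(n, 16.0), np.full(n, 8.0), np.full(n, 8.0)], axis=1)}
        scores = np.linspace(0.1, 0.9, n)[:, None]
        out = decode_detections({3: scores}, {3: np.zeros((n, 4))}, anchors, 0.05, 0.3)
        assert len(out) == 200
        got = [b.score for b in out]
        assert got == sorted(got, reverse=True)
        assert min(got) >= float(scores[50, 0])  # the weakest 50 were dropped

    def test_score_sorted_and_capped_on_random_inputs(self):
        rng = np.random.default_rng(0)
        n = 400
        anchors = {3: np.stack([
            rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
            np.full(n, 8.0), np.full(n, 8.0)], axis=1)}
        scores = rng.uniform(0, 1, (n, 1))
        out = decode_detections({3: scores}, {3: rng.normal(0, 0.1, (n, 4))}, anchors, 0.05, 0.5)
        assert len(out) <= 200
        got = [b.score for b in out]
        assert got == sorted(got, reverse=True)


class TestBoxesToPoints:
    def test_rounding_and_axis_convention(self):
        (pt,) = boxes_to_points([DetectionBox(10.4, 20.6, 8, 8, 0.5)])
        assert (pt.row, pt.col) == (21, 10)

    def test_empty_and_count(self):
        assert boxes_to_points([]) == []
        boxes = [DetectionBox(float(i), float(i), 4, 4, 0.1) for i in range(5)]
        assert len(boxes_to_points(boxes)) == 5


class TestTraining:
    def test_initial_loss_matches_hand_computation(self, tree):
        """Single-batch oracle: the first recorded loss equals focal +
        smooth-L1 computed directly from the initial forward pass."""
        from retinareg.junction_detection import (
            PYRAMID_LEVELS,
            _anchor_pack,
            _assign_anchors,
            _box_targets,
            _flatten_level,
            train_jdn,
        )

        mask, junctions = tree
        cfg = JDNConfig(steps=1, batch_size=1, seed=0)
        model = JDN(cfg)

        # independent loss computation from the initial forward pass
        arr = mask.mask.astype(np.float32)
        packs = _anchor_pack(cfg, arr.shape[0])
        flat = np.concatenate([packs[l] for l in PYRAMID_LEVELS])
        side = cfg.gt_box_size * arr.shape[0] / cfg.reference_size
        gt = np.array([[j.col, j.row, side, side] for j in junctions])
        labels, ignore, matched = _assign_anchors(flat, gt, cfg.pos_iou, cfg.neg_iou)
        box_t = _box_targets(flat, gt[matched])
        model.train()
        cls_out, box_out = model.forward(arr[None, None])
        logits = np.concatenate(
            [_flatten_level(cls_out[l].data[0], 1) for l in sorted(cls_out)]
        ).ravel()
        deltas = np.concatenate(
            [_flatten_level(box_out[l].data[0], 4) for l in sorted(box_out)]
        )
        n_pos = max(1.0, (labels == 1).sum())
        p = 1 / (1 + np.exp(-logits.astype(np.float64)))
        pt = np.where(labels == 1, p, 1 - p)
        at = np.where(labels == 1, cfg.focal_alpha, 1 - cfg.focal_alpha)
        fl = -(at * (1 - pt) ** cfg.focal_gamma * np.log(pt))[~ignore].sum() / n_pos
        d = deltas - box_t
        sl1 = np.where(np.abs(d) < 1, 0.5 * d * d, np.abs(d) - 0.5)
        sl1 = sl1[labels == 1].sum() / n_pos
        expected = fl + sl1

        model2 = JDN(cfg)  # same seed -> identical initialization
        _, history = train_jdn(model2, [(mask, junctions)], cfg)
        assert history[0] == pytest.approx(expected, rel=1e-3)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            from retinareg.junction_detection import train_jdn

            train_jdn(JDN(JDNConfig()), [], JDNConfig())
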