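import numpy as np
import pytest

from retinareg.nn import Tensor
from retinareg.synthetic import synthetic_patches
from retinareg.types import FundusImage, VesselMask
from retinareg.vessel_segmentation import (
    ConnectedConvBlock,
    VSN,
    VSNConfig,
    build_vsn,
    fallback_segment,
    load_vsn,
    save_vsn,
    segment_vessels,
    train_vsn,
)


@pytest.fixture(scope="module")
def small_cfg():
    return VSNConfig(levels=3, base_channels=8, epochs=1, learning_rate=1e-3, seed=0)


@pytest.fixture(scope="module")
def small_model(small_cfg):
    return build_vsn(small_cfg)


class TestArchitecture:
    def test_output_shape_matches_input(self, small_model):
        x = np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)
        assert small_model.forward(x).shape == (1, 2, 64, 64)

    def test_encoder_halves_each_level(self, small_model):
        """Walk the encoder by hand: each downsampling step halves the
        spatial size, so a 64-px input reaches 8 px after 3 levels."""
        x = np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)
        feats = Tensor(x)
        sizes = []
        for i in range(small_model.config.levels):
            if i > 0 and small_model.config.use_multi_input:
                feats = small_model.multi_input_fuse(i, x, feats)
            feats = small_model.enc_blocks[i](feats)
            if small_model.cc_blocks[i] is not None:
                feats = small_model.cc_blocks[i](feats)
            feats = small_model.down_convs[i](feats)
            sizes.append(feats.data.shape[-1])
        assert sizes == [32, 16, 8]

    def test_deepest_map_is_input_over_two_pow_levels(self):
        cfg = VSNConfig(levels=4, base_channels=4, seed=0)
        model = build_vsn(cfg)
        x = np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)
        feats = Tensor(x)
        for i in range(4):
            if i > 0:
                feats = model.multi_input_fuse(i, x, feats)
            feats = model.enc_blocks[i](feats)
            feats = model.cc_blocks[i](feats)
            feats = model.down_convs[i](feats)
        assert feats.data.shape[-2:] == (4, 4)

    def test_indivisible_size_names_requirement(self, small_model):
        x = np.zeros((1, 1, 60, 60), dtype=np.float32)
        with pytest.raises(ValueError, match="divisible by 8"):
            small_model.forward(x)

    def test_connected_conv_increases_parameter_count(self):
        on = build_vsn(VSNConfig(levels=2, base_channels=8, use_connected_conv=True))
        off = build_vsn(VSNConfig(levels=2, base_channels=8, use_connected_conv=False))
        assert on.n_parameters() > off.n_parameters()

    def test_module_flags_change_forward_output(self):
        x = np.random.default_rng(1).random((1, 1, 32, 32), dtype=np.float32)
        outs = []
        for mi, cc in [(True, True), (False, True), (True, False)]:
            m = build_vsn(
                VSNConfig(levels=2, base_channels=8, use_multi_input=mi,
                          use_connected_conv=cc, seed=0)
            )
            m.eval()
            outs.append(m.forward(x).data)
        assert not np.allclose(outs[0], outs[1])
        assert outs[0].shape != outs[2].shape or not np.allclose(outs[0], outs[2])


class TestMultiInputFuse:
    def test_channel_arithmetic(self, small_model):
        x = np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)
        feats = Tensor(np.random.default_rng(1).random((1, 8, 32, 32), dtype=np.float32))
        fused = small_model.multi_input_fuse(1, x, feats)
        img_ch = fused.data.shape[1] - 8
        assert img_ch >= 4
        assert fused.data.shape[-2:] == (32, 32)

    def test_level_zero_rejected(self, small_model):
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        with pytest.raises(ValueError):
            small_model.multi_input_fuse(0, x, Tensor(x))

    def test_sensitive_to_image_perturbation(self, small_model):
        """The fused features must respond to the raw image even when the
        incoming level features are held fixed."""
        rng = np.random.default_rng(0)
        x = rng.random((1, 1, 64, 64), dtype=np.float32)
        feats = Tensor(rng.random((1, 8, 32, 32), dtype=np.float32))
        small_model.eval()
        a = small_model.multi_input_fuse(1, x, feats).data
        b = small_model.multi_input_fuse(1, x + 0.5, feats).data
        assert not np.allclose(a, b)


class TestConnectedConv:
    def test_concatenation_arithmetic(self):
        block = ConnectedConvBlock(6, 6, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).random((1, 6, 16, 16), dtype=np.float32))
        out = block(x)
        assert out.data.shape == (1, 12, 16, 16)

    def test_zero_input_passes_zeros_through_copied_slice(self):
        block = ConnectedConvBlock(4, 4, rng=np.random.default_rng(0))
        block.eval()
        out = block(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))
        np.testing.assert_array_equal(out.data[:, :4], 0.0)

    def test_gradient_reaches_both_branches(self):
        block = ConnectedConvBlock(4, 4, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(0, 1, (1, 4, 8, 8)), True)
        out = block(x)
        out.backward(np.ones_like(out.data))
        assert x.grad is not None and np.abs(x.grad).sum() > 0
        assert block.stage1.conv.weight.grad is not None
        assert np.abs(block.stage1.conv.weight.grad).sum() > 0


class TestTraining:
    def test_zero_epochs_is_noop(self, small_cfg):
        cfg = VSNConfig(**{**small_cfg.__dict__, "epochs": 0})
        model = build_vsn(cfg)
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        data = synthetic_patches(2, 64, seed=0)
        model, history = train_vsn(model, data, cfg)
        assert history == []
        for k, v in model.state_arrays().items():
            np.testing.assert_array_equal(v, before[k])

    def test_overfits_single_patch(self):
        data = synthetic_patches(1, 64, seed=1)
        cfg = VSNConfig(levels=3, base_channels=8, epochs=40, learning_rate=2e-3,
                        batch_size=1, augment_training=False, seed=0)
        model, history = train_vsn(build_vsn(cfg), data, cfg)
        assert history[-1] <= 0.5 * history[0]

    def test_same_seed_same_loss(self):
        data = synthetic_patches(2, 64, seed=2)
        cfg = VSNConfig(levels=2, base_channels=4, epochs=2, learning_rate=1e-3,
                        batch_size=2, seed=7)
        _, h1 = train_vsn(build_vsn(cfg), data, cfg)
        _, h2 = train_vsn(build_vsn(cfg), data, cfg)
        assert h1 == h2

    def test_nonbinary_mask_rejected(self, small_cfg):
        img = np.zeros((64, 64), dtype=np.float32)
        bad = np.full((64, 64), 2, dtype=np.int64)
        with pytest.raises(ValueError):
            train_vsn(build_vsn(small_cfg), [(img, bad)], small_cfg)


class TestSegmentation:
    def test_threshold_extremes(self, small_model, fundus):
        prob, ones = segment_vessels(small_model, fundus, threshold=0.0)
        assert ones.mask.min() == 1
        _, zeros = segment_vessels(small_model, fundus, threshold=1.0 + 1e-9)
        assert zeros.mask.max() == 0

    def test_fallback_f1_on_phantom(self, tree, fundus):
        mask, _ = tree
        _, pred = fallback_segment(fundus)
        tp = int(((pred.mask == 1) & (mask.mask == 1)).sum())
        fp = int(((pred.mask == 1) & (mask.mask == 0)).sum())
        fn = int(((pred.mask == 0) & (mask.mask == 1)).sum())
        assert 2 * tp / (2 * tp + fp + fn) >= 0.7

    def test_checkpoint_roundtrip(self, tmp_path, small_cfg):
        model = build_vsn(small_cfg)
        x = np.random.default_rng(0).random((64, 64), dtype=np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "vsn.npz"
        save_vsn(model, path)
        restored = load_vsn(path)
        np.testing.assert_allclose(restored.predict_proba(x), before, atol=1e-6)
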