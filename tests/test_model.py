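"""Architecture contracts: shapes, the vessel gate, gradient paths."""

import numpy as np
import pytest

from fundusmtl.model import (ModelConfig, VesselGuidedNet, as_input_tensor,
                             load_checkpoint, save_checkpoint, vessel_gate)
from fundusmtl.losses import dice_loss, weighted_bce
from fundusmtl.nn import Tensor, no_grad

TINY = ModelConfig(stage_channels=(2, 3, 4, 5), hidden_dim=8, num_classes=2,
                   dropout_rate=0.0)


def rand_image(size=64, seed=0, n=1):
    return np.random.default_rng(seed).random((n, size, size, 3),
                                              dtype=np.float32)


class TestConfig:
    def test_stage_count_enforced(self):
        with pytest.raises(ValueError, match="four"):
            ModelConfig(stage_channels=(8, 16, 32))

    def test_channels_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ModelConfig(stage_channels=(8, 8, 16, 32))

    def test_presets(self):
        toy = ModelConfig.preset("toy")
        full = ModelConfig.preset("full")
        assert toy.stage_channels == (8, 16, 32, 64)
        assert full.stage_channels == (256, 512, 1024, 2048)
        assert full.blocks_per_stage == (3, 4, 6, 3)

    def test_parameter_count_introspection(self):
        net = VesselGuidedNet(TINY, init_seed=0)
        total = sum(p.data.size for p in net.parameters())
        assert net.num_parameters() == total > 0


class TestEncoder:
    @pytest.mark.parametrize("size", [64, 96, 128, 224])
    def test_pyramid_shape_algebra(self, size):
        net = VesselGuidedNet(TINY, init_seed=0)
        with no_grad():
            pyr = net.encode(as_input_tensor(rand_image(size)))
        assert pyr["stem"].shape[2:] == (size // 2, size // 2)
        for i in range(1, 5):
            stride = 4 * 2 ** (i - 1)
            f = pyr[f"f{i}"]
            assert f.shape[2:] == (size // stride, size // stride)
            assert f.shape[1] == TINY.stage_channels[i - 1]
            assert np.isfinite(f.data).all()

    def test_indivisible_size_rejected_with_named_constraint(self):
        net = VesselGuidedNet(TINY, init_seed=0)
        with pytest.raises(ValueError, match="divisible by 32"):
            net.encode(as_input_tensor(np.zeros((1, 60, 60, 3),
                                                dtype=np.float32)))

    def test_zero_input_biasfree_gives_zero_pyramid(self):
        cfg = ModelConfig(stage_channels=(2, 3, 4, 5), hidden_dim=8,
                          conv_bias=False, dropout_rate=0.0)
        net = VesselGuidedNet(cfg, init_seed=1)
        with no_grad():
            pyr = net.encode(as_input_tensor(np.zeros((1, 64, 64, 3),
                                                      dtype=np.float32)))
        for key in ("stem", "f1", "f2", "f3", "f4"):
            assert np.abs(pyr[key].data).max() == 0.0

    def test_eval_mode_is_deterministic(self):
        net = VesselGuidedNet(TINY, init_seed=2).eval()
        x = rand_image(64, seed=3)
        with no_grad():
            a = net(x)
            b = net(x)
        assert np.array_equal(a.seg.data, b.seg.data)
        assert np.array_equal(a.probs.data, b.probs.data)


class TestSegmentationDecoder:
    @pytest.mark.parametrize("size", [64, 96])
    def test_output_matches_input_resolution(self, size):
        net = VesselGuidedNet(TINY, init_seed=0)
        with no_grad():
            out = net(rand_image(size, seed=1))
        assert out.seg.shape == (1, 1, size, size)
        assert out.seg.data.min() >= 0.0 and out.seg.data.max() <= 1.0

    def test_zero_weights_give_constant_sigmoid_of_bias(self):
        net = VesselGuidedNet(TINY, init_seed=0)
        bias_value = 0.7
        for name, p in net.named_parameters():
            if name.startswith(("up", "seg_head")):
                p.data = np.zeros_like(p.data)
        net.seg_head.bias.data = np.full(1, bias_value, dtype=np.float32)
        with no_grad():
            out = net(rand_image(64, seed=2))
        expected = 1.0 / (1.0 + np.exp(-bias_value))
        assert np.allclose(out.seg.data, expected, atol=1e-6)


class TestVesselGate:
    def test_identity_mask_passes_features_through(self):
        f4 = Tensor(np.random.default_rng(0).random((1, 3, 2, 2),
                                                    dtype=np.float32))
        m = Tensor(np.ones((1, 1, 64, 64), dtype=np.float32))
        gated = vessel_gate(f4, m)
        assert np.allclose(gated.data, f4.data, atol=1e-6)

    def test_zero_mask_zeroes_features(self):
        f4 = Tensor(np.random.default_rng(1).random((1, 3, 2, 2),
                                                    dtype=np.float32))
        m = Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert np.abs(vessel_gate(f4, m).data).max() == 0.0

    def test_matches_elementwise_oracle_with_average_pooling(self):
        rng = np.random.default_rng(2)
        f4 = rng.random((2, 3, 2, 2), dtype=np.float32)
        m = rng.random((2, 1, 8, 8), dtype=np.float32)
        gated = vessel_gate(Tensor(f4), Tensor(m))
        # oracle: average 4x4 blocks, broadcast multiply
        pooled = m.reshape(2, 1, 2, 4, 2, 4).mean(axis=(3, 5))
        assert np.allclose(gated.data, f4 * pooled, atol=1e-6)

    def test_out_of_range_mask_rejected(self):
        f4 = Tensor(np.ones((1, 1, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            vessel_gate(f4, Tensor(np.full((1, 1, 4, 4), 1.5,
                                           dtype=np.float32)))


class TestClassificationHead:
    def test_zero_feature_zero_weights_give_half(self):
        net = VesselGuidedNet(TINY, init_seed=0)
        net.fc1.weight.data = np.zeros_like(net.fc1.weight.data)
        net.fc1.bias.data = np.zeros_like(net.fc1.bias.data)
        net.fc2.weight.data = np.zeros_like(net.fc2.weight.data)
        net.fc2.bias.data = np.zeros_like(net.fc2.bias.data)
        net.eval()
        with no_grad():
            out = net(rand_image(64, seed=4))
        assert np.allclose(out.probs.data, 0.5, atol=1e-7)

    def test_fusion_disabled_ignores_segmentation(self):
        cfg = ModelConfig(stage_channels=(2, 3, 4, 5), hidden_dim=8,
                          num_classes=2, dropout_rate=0.0,
                          fusion_enabled=False)
        net = VesselGuidedNet(cfg, init_seed=5).eval()
        x = rand_image(64, seed=6)
        with no_grad():
            base = net(x).probs.data.copy()
            # perturb the whole segmentation decoder; logits must not move
            for name, p in net.named_parameters():
                if name.startswith(("up", "seg_head")):
                    p.data = p.data + 1.0
            perturbed = net(x).probs.data
        assert np.array_equal(base, perturbed)

    def test_toy_head_logit_is_hand_computed_dot_product(self):
        # single-class head on a 2-dim fused feature with known weights
        from fundusmtl.nn import Linear, Tensor as T
        rng = np.random.default_rng(0)
        fc = Linear(2, 1, rng=rng)
        fc.weight.data = np.array([[0.5], [-2.0]], dtype=np.float32)
        fc.bias.data = np.array([0.25], dtype=np.float32)
        feat = np.array([[0.3, 0.7]], dtype=np.float32)
        logit = fc(T(feat)).data[0, 0]
        assert logit == pytest.approx(0.3 * 0.5 + 0.7 * (-2.0) + 0.25,
                                      rel=1e-6)


class TestGradientPaths:
    def _cls_grad_on_decoder(self, fusion, stop_grad):
        cfg = ModelConfig(stage_channels=(2, 3, 4, 5), hidden_dim=8,
                          num_classes=2, dropout_rate=0.0,
                          fusion_enabled=fusion,
                          mask_stop_gradient=stop_grad)
        net = VesselGuidedNet(cfg, init_seed=7)
        out = net(rand_image(64, seed=8))
        loss = weighted_bce(out.probs, np.array([[1.0, 0.0]]))
        net.zero_grad()
        loss.backward()
        return max(np.abs(p.grad).max()
                   for name, p in net.named_parameters()
                   if name.startswith(("up", "seg_head"))
                   and p.grad is not None
                   ) if any(p.grad is not None
                            for name, p in net.named_parameters()
                            if name.startswith(("up", "seg_head"))) else 0.0

    def test_cls_loss_reaches_decoder_iff_gated_without_stop(self):
        assert self._cls_grad_on_decoder(fusion=True, stop_grad=False) > 0
        assert self._cls_grad_on_decoder(fusion=True, stop_grad=True) == 0
        assert self._cls_grad_on_decoder(fusion=False, stop_grad=False) == 0

    def test_seg_loss_never_reaches_classification_head(self):
        net = VesselGuidedNet(TINY, init_seed=9)
        out = net(rand_image(64, seed=10))
        target = np.zeros((1, 1, 64, 64), dtype=np.float32)
        net.zero_grad()
        dice_loss(out.seg, target).backward()
        for name, p in net.named_parameters():
            if name.startswith("fc"):
                assert p.grad is None

    def test_logit_gradient_matches_finite_differences(self):
        # toy instance (< 1e3 parameters): gradient of a class logit w.r.t.
        # a stem weight agrees with central differences
        cfg = ModelConfig(stage_channels=(2, 3, 4, 5), hidden_dim=4,
                          num_classes=1, dropout_rate=0.0)
        net = VesselGuidedNet(cfg, init_seed=11)
        net.eval()        # fixed normalization statistics
        assert net.num_parameters() < 10_000
        x = rand_image(64, seed=12)

        def logit():
            out = net(x)
            return float(out.logits.data[0, 0])

        out = net(x)
        net.zero_grad()
        out.logits.sum().backward()
        w = net.stem.weight
        analytic = w.grad[0, 0, 0, 0]
        eps = 1e-2
        orig = float(w.data[0, 0, 0, 0])
        w.data[0, 0, 0, 0] = orig + eps
        up = logit()
        w.data[0, 0, 0, 0] = orig - eps
        down = logit()
        w.data[0, 0, 0, 0] = orig
        numeric = (up - down) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-2, abs=1e-6)


class TestCheckpointing:
    def test_round_trip_preserves_outputs(self, tmp_path):
        net = VesselGuidedNet(TINY, init_seed=13).eval()
        x = rand_image(64, seed=14)
        with no_grad():
            before = net(x).probs.data.copy()
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, str(path), extra={"note": "test"})
        loaded, extra = load_checkpoint(str(path))
        loaded.eval()
        assert extra == {"note": "test"}
        with no_grad():
            after = loaded(x).probs.data
        assert np.array_equal(before, after)

    def test_state_dict_mismatch_detected(self):
        net = VesselGuidedNet(TINY, init_seed=0)
        state = net.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(KeyError, match="missing"):
            net.load_state_dict(state)
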