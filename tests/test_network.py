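import numpy as np
import pytest

from edgeunet.losses import multitask_loss
from edgeunet.network import (EdgeAwareUNet, ModelConfig, build_model,
                              count_parameters)
from edgeunet.nn import Adam
from edgeunet.trainer import _batch_targets


def tiny_model(variant="full", size=32, b=4, seed=0):
    return build_model(input_size=size, base_channels=b, variant=variant,
                       seed=seed)


class TestShapes:
    def test_reference_scale_output_heads(self):
        # full model at 256 gives seg (256,256,1), boundary heads
        # (64,64,1)/(32,32,1) and edge maps (32,32,1)/(64,64,1)
        m = build_model(input_size=256, base_channels=64, variant="full")
        shapes = {name: shape for name, _, shape in m.layer_table()}
        assert shapes["seg_output"] == (256, 256, 1)
        assert shapes["boundary_output1"] == (64, 64, 1)
        assert shapes["boundary_output2"] == (32, 32, 1)
        assert shapes["edge_output4"] == (32, 32, 1)
        assert shapes["edge_output7"] == (64, 64, 1)
        assert shapes["conv2d"] == (256, 256, 64)
        assert shapes["conv2d_8"] == (16, 16, 1024)

    def test_smaller_input_scales_head_ratios(self):
        m = tiny_model(size=64, b=8)
        out = m.forward(np.zeros((1, 64, 64), np.float32))
        assert out.seg.shape == (1, 64, 64)
        assert out.boundary_aux[4].shape == (1, 16, 16)
        assert out.boundary_aux[8].shape == (1, 8, 8)

    def test_baseline_variant_returns_seg_only(self):
        m = tiny_model("baseline")
        out = m.forward(np.zeros((2, 32, 32), np.float32))
        assert out.boundary_aux == {} and out.edge_attn == {}
        assert out.seg.shape == (2, 32, 32)

    @pytest.mark.parametrize("kwargs", [
        {"input_size": 100},
        {"variant": "unknown"},
        {"base_channels": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**{"input_size": 64, **kwargs})

    def test_wrong_batch_shape_rejected(self):
        m = tiny_model()
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 16, 16), np.float32))
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 32, 32, 3), np.float32))


class TestParameterCount:
    @staticmethod
    def conv_params(k, cin, cout, bn=True):
        n = k * k * cin * cout + cout
        return n + (2 * cout if bn else 0)

    def test_baseline_matches_closed_form(self):
        b = 8
        m = tiny_model("baseline", b=b)
        c = self.conv_params
        expected = (
            c(3, 1, b) +                                  # enc1
            c(3, b, 2 * b) + c(3, 2 * b, 2 * b) +          # enc2
            c(3, 2 * b, 4 * b) + c(3, 4 * b, 4 * b) +      # enc3
            c(3, 4 * b, 8 * b) + c(3, 8 * b, 8 * b) +      # enc4
            c(3, 8 * b, 16 * b) + c(3, 16 * b, 16 * b) +   # bottleneck
            c(2, 16 * b, 8 * b, bn=False) +                # up1
            c(3, 16 * b, 8 * b) + c(3, 8 * b, 8 * b) +     # dec1
            c(2, 8 * b, 4 * b, bn=False) +                 # up2
            c(3, 8 * b, 4 * b) + c(3, 4 * b, 4 * b) +      # dec2
            c(2, 4 * b, 2 * b, bn=False) +                 # up3
            c(3, 4 * b, 2 * b) + c(3, 2 * b, 2 * b) +      # dec3
            c(2, 2 * b, b, bn=False) +                     # up4
            c(3, 2 * b, b) + c(3, b, b) +                  # dec4
            c(1, b, 1, bn=False)                           # seg head
        )
        assert count_parameters(m) == expected

    def test_full_variant_is_superset_of_baseline(self):
        assert count_parameters(tiny_model("full")) > \
            count_parameters(tiny_model("baseline"))

    def test_doubling_width_roughly_quadruples_parameters(self):
        small = count_parameters(tiny_model("baseline", b=4))
        big = count_parameters(tiny_model("baseline", b=8))
        assert 3.5 < big / small < 4.5


class TestForward:
    def test_outputs_are_probabilities(self, rng):
        m = tiny_model()
        out = m.forward(rng.random((2, 32, 32)).astype(np.float32))
        for arr in [out.seg, *out.boundary_aux.values(),
                    *out.edge_attn.values()]:
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_identical_batch_rows_give_identical_outputs(self, rng):
        m = tiny_model()
        img = rng.random((32, 32)).astype(np.float32)
        out = m.forward(np.stack([img, img]))
        assert np.array_equal(out.seg[0], out.seg[1])

    def test_same_seed_builds_identical_models(self, rng):
        img = rng.random((1, 32, 32)).astype(np.float32)
        a = tiny_model(seed=11).forward(img).seg
        b = tiny_model(seed=11).forward(img).seg
        assert np.array_equal(a, b)

    def test_translation_equivariance_on_pool_aligned_shift(self, rng):
        # shifting the input by a pooling-aligned offset must shift the
        # output identically away from borders — guards against any
        # accidental spatial flattening
        m = tiny_model(size=64, b=4)
        img = np.zeros((64, 64), np.float32)
        img[10:20, 12:22] = 1.0
        shift = 16
        seg = m.forward(img[None]).seg[0]
        seg_shifted = m.forward(np.roll(img, shift, axis=0)[None]).seg[0]
        rolled = np.roll(seg, shift, axis=0)
        core = np.s_[24:56, 4:60]
        assert seg.std() > 1e-4  # not spatially constant
        # border effects of zero-padded convolutions leak inward through
        # the deep receptive field; the interior still tracks the shift
        assert np.abs(seg_shifted[core] - rolled[core]).max() < 0.02
        assert np.abs(seg_shifted - rolled).max() < 10 * seg.std()


class TestTraining:
    def test_every_parameter_receives_gradient(self, rng):
        m = tiny_model()
        imgs = rng.random((4, 32, 32)).astype(np.float32)
        masks = (rng.random((4, 32, 32)) < 0.4).astype(np.uint8)
        x = m._to_tensor(imgs)
        preds = m._forward(x, training=True)
        targets = _batch_targets(masks, (4, 8), bso=True)
        loss, _ = multitask_loss(preds, targets)
        opt = Adam(m.parameters())
        opt.zero_grad()
        loss.backward()
        for name, p in m.named_parameters():
            assert p.grad is not None and np.linalg.norm(p.grad) > 0, name

    def test_save_load_roundtrip_preserves_outputs(self, rng, tmp_path):
        m = tiny_model(seed=3)
        img = rng.random((1, 32, 32)).astype(np.float32)
        before = m.forward(img).seg
        m.save(tmp_path / "ckpt.npz")
        restored = EdgeAwareUNet.load(tmp_path / "ckpt.npz")
        assert restored.config == m.config
        assert np.array_equal(restored.forward(img).seg, before)

    def test_summary_lists_heads(self):
        text = tiny_model().summary()
        assert "seg_output" in text and "Trainable parameters" in text
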