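"""Edge-aware U-Net: encoder-decoder segmentation with Sobel edge
attention and multi-scale boundary supervision.

Reference topology (variant ``full`` at 256x256x1 input, base width 64):

* Encoder: conv(64) -> pool -> 2x conv(128) -> pool -> 2x conv(256) ->
  pool -> 2x conv(512). Each conv is Conv -> BatchNorm -> ReLU.
* At the 1/8 level a fixed Sobel layer produces a single-channel edge
  magnitude; a 1x1 convolution + sigmoid turns it into an attention map
  E4 (32, 32, 1) which is broadcast-multiplied with the 512-channel
  features and concatenated with them (-> 1024 channels).
* Bottleneck: pool -> 2x conv(1024) with dilation rate 2.
* Decoder: transposed conv to 1/8 (512), skip-concat (-> 1536),
  2x conv(512); up to 1/4 (256), skip-concat, conv(256), a second Sobel
  attention E7 (64, 64, 1) multiplies/concatenates, conv(256); up to
  1/2 (128) and full resolution (64), each with skip-concat + 2x conv.
* Heads: sigmoid segmentation at full resolution; sigmoid boundary
  heads at 1/4 (64, 64, 1) and 1/8 (32, 32, 1); the two attention maps
  are exposed as edge outputs. Skip fusion is by concatenation.

Ablation variants: ``baseline`` strips the Sobel attention and the
auxiliary heads (a plain U-Net); ``edge_only`` keeps the full topology
but is meant to train without the boundary-sensitive loss;
``boundary_only`` is the baseline topology trained with the
boundary-sensitive loss. The variant only changes topology here — the
trainer selects the loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, maxpool2, no_grad
from .nn import (Adam, BatchNorm2D, Conv2D, ConvTranspose2D, Module,
                 sobel_magnitude_t)

__all__ = ["ModelConfig", "NetworkOutputs", "EdgeAwareUNet", "build_model",
           "count_parameters"]

VARIANTS = ("baseline", "edge_only", "boundary_only", "full")


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 256
    input_channels: int = 1
    base_channels: int = 64
    variant: str = "full"
    dilation_rate_bottleneck: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 16:
            raise ValueError("input_size must be divisible by 16 "
                             "(four pooling stages)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.base_channels < 1 or self.input_channels < 1:
            raise ValueError("channel counts must be positive")

    @property
    def has_attention(self) -> bool:
        return self.variant in ("full", "edge_only")

    @property
    def uses_bso_loss(self) -> bool:
        return self.variant in ("full", "boundary_only")


@dataclass
class NetworkOutputs:
    """Forward-pass outputs as NumPy arrays.

    ``seg``: (N, H, W) probabilities at input resolution.
    ``boundary_aux``: {downsample factor: (N, H/f, W/f) probabilities}
    (factors 4 and 8 for the reference model; empty for baseline).
    ``edge_attn``: {factor: (N, H/f, W/f) attention maps in (0, 1)}.
    """

    seg: np.ndarray
    boundary_aux: dict[int, np.ndarray] = field(default_factory=dict)
    edge_attn: dict[int, np.ndarray] = field(default_factory=dict)


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, rng, dilation=1):
        self.conv = Conv2D(cin, cout, k=3, dilation=dilation, rng=rng)
        self.bn = BatchNorm2D(cout)

    def __call__(self, x, training):
        return self.bn(self.conv(x), training).relu()


class EdgeAwareUNet(Module):
    """The segmentation model. Build from a :class:`ModelConfig`, call
    :meth:`fit` to train (delegates to :mod:`edgeunet.trainer`), and
    :meth:`forward` / :meth:`predict` for inference."""

    def __init__(self, config: ModelConfig | None = None, **kwargs):
        cfg = config or ModelConfig(**kwargs)
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_channels
        cin = cfg.input_channels
        att = cfg.has_attention
        d = cfg.dilation_rate_bottleneck

        self.enc1 = [_ConvBNReLU(cin, b, rng)]
        self.enc2 = [_ConvBNReLU(b, 2 * b, rng), _ConvBNReLU(2 * b, 2 * b, rng)]
        self.enc3 = [_ConvBNReLU(2 * b, 4 * b, rng), _ConvBNReLU(4 * b, 4 * b, rng)]
        self.enc4 = [_ConvBNReLU(4 * b, 8 * b, rng), _ConvBNReLU(8 * b, 8 * b, rng)]
        if att:
            # near-zero init keeps the gate neutral (E ~ 0.5) at the start
            # of training instead of randomly saturating on large Sobel
            # magnitudes of deep features
            self.attn4 = Conv2D(1, 1, k=1, rng=rng, init_std=0.05)
        skip4 = 16 * b if att else 8 * b
        self.bott = [_ConvBNReLU(skip4, 16 * b, rng, dilation=d),
                     _ConvBNReLU(16 * b, 16 * b, rng, dilation=d)]
        self.up1 = ConvTranspose2D(16 * b, 8 * b, rng=rng)
        self.dec1 = [_ConvBNReLU(8 * b + skip4, 8 * b, rng),
                     _ConvBNReLU(8 * b, 8 * b, rng)]
        self.up2 = ConvTranspose2D(8 * b, 4 * b, rng=rng)
        self.dec2a = _ConvBNReLU(8 * b, 4 * b, rng)
        if att:
            self.attn7 = Conv2D(1, 1, k=1, rng=rng, init_std=0.05)
            self.dec2b = _ConvBNReLU(8 * b, 4 * b, rng)
        else:
            self.dec2b = _ConvBNReLU(4 * b, 4 * b, rng)
        self.up3 = ConvTranspose2D(4 * b, 2 * b, rng=rng)
        self.dec3 = [_ConvBNReLU(4 * b, 2 * b, rng), _ConvBNReLU(2 * b, 2 * b, rng)]
        self.up4 = ConvTranspose2D(2 * b, b, rng=rng)
        self.dec4 = [_ConvBNReLU(2 * b, b, rng), _ConvBNReLU(b, b, rng)]
        self.seg_head = Conv2D(b, 1, k=1, rng=rng)
        if att:
            self.boundary_head1 = Conv2D(4 * b, 1, k=1, rng=rng)  # 1/4 scale
            self.boundary_head2 = Conv2D(8 * b, 1, k=1, rng=rng)  # 1/8 scale

    # ------------------------------------------------------------- forward

    def _attention(self, head: Conv2D, x: Tensor) -> Tensor:
        return head(sobel_magnitude_t(x)).sigmoid()

    def _forward(self, x: Tensor, training: bool,
                 trace: list | None = None) -> dict:
        cfg = self.config
        att = cfg.has_attention

        def log(name, kind, t):
            if trace is not None:
                trace.append((name, kind, tuple(t.shape[1:])))

        log("input", "InputLayer", x)
        x1 = self.enc1[0](x, training); log("conv2d", "Conv2D", x1)
        p1 = maxpool2(x1); log("pool1", "MaxPooling2D", p1)
        x2 = p1
        for i, blk in enumerate(self.enc2):
            x2 = blk(x2, training); log(f"conv2d_{2 + i}", "Conv2D", x2)
        p2 = maxpool2(x2); log("pool2", "MaxPooling2D", p2)
        x3 = p2
        for i, blk in enumerate(self.enc3):
            x3 = blk(x3, training); log(f"conv2d_{4 + i}", "Conv2D", x3)
        p3 = maxpool2(x3); log("pool3", "MaxPooling2D", p3)
        x4 = p3
        for i, blk in enumerate(self.enc4):
            x4 = blk(x4, training); log(f"conv2d_{6 + i}", "Conv2D", x4)
        if att:
            e4 = self._attention(self.attn4, x4); log("lambda", "Lambda", e4)
            mul4 = x4 * e4; log("multiply", "Multiply", mul4)
            fused4 = concat([x4, mul4]); log("concat1", "Concatenate", fused4)
        else:
            fused4 = x4
        p4 = maxpool2(fused4); log("pool4", "MaxPooling2D", p4)
        xb = p4
        for i, blk in enumerate(self.bott):
            xb = blk(xb, training); log(f"conv2d_{8 + i}", "Conv2D", xb)
        u1 = self.up1(xb); log("conv2d_transpose", "Conv2DTranspose", u1)
        d1 = concat([u1, fused4]); log("concat2", "Concatenate", d1)
        for i, blk in enumerate(self.dec1):
            d1 = blk(d1, training); log(f"conv2d_{10 + i}", "Conv2D", d1)
        u2 = self.up2(d1); log("conv2d_transpose_1", "Conv2DTranspose", u2)
        d2 = concat([u2, x3]); log("concat3", "Concatenate", d2)
        d2 = self.dec2a(d2, training); log("conv2d_12", "Conv2D", d2)
        if att:
            e7 = self._attention(self.attn7, d2); log("lambda_1", "Lambda", e7)
            mul7 = d2 * e7; log("multiply_1", "Multiply", mul7)
            d2 = concat([d2, mul7]); log("concat4", "Concatenate", d2)
        d2 = self.dec2b(d2, training); log("conv2d_13", "Conv2D", d2)
        u3 = self.up3(d2); log("conv2d_transpose_2", "Conv2DTranspose", u3)
        d3 = concat([u3, x2]); log("concat5", "Concatenate", d3)
        for i, blk in enumerate(self.dec3):
            d3 = blk(d3, training); log(f"conv2d_{14 + i}", "Conv2D", d3)
        u4 = self.up4(d3); log("conv2d_transpose_3", "Conv2DTranspose", u4)
        d4 = concat([u4, x1]); log("concat6", "Concatenate", d4)
        for i, blk in enumerate(self.dec4):
            d4 = blk(d4, training); log(f"conv2d_{16 + i}", "Conv2D", d4)
        seg = self.seg_head(d4).sigmoid(); log("seg_output", "Conv2D", seg)
        out = {"seg": seg, "boundary": {}, "edge": {}}
        if att:
            b1 = self.boundary_head1(d2).sigmoid()
            log("boundary_output1", "Conv2D", b1)
            b2 = self.boundary_head2(d1).sigmoid()
            log("boundary_output2", "Conv2D", b2)
            log("edge_output4", "Lambda", e4)
            log("edge_output7", "Lambda", e7)
            out["boundary"] = {4: b1, 8: b2}
            out["edge"] = {8: e4, 4: e7}
        return out

    def _to_tensor(self, batch: np.ndarray) -> Tensor:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[..., None]
        if batch.ndim != 4:
            raise ValueError(f"expected (N, H, W[, C]) batch, got {batch.shape}")
        n, h, w, c = batch.shape
        s = self.config.input_size
        if (h, w) != (s, s):
            raise ValueError(f"batch spatial dims {(h, w)} != input_size {s}")
        if c != self.config.input_channels:
            raise ValueError(
                f"batch has {c} channels, model expects "
                f"{self.config.input_channels}")
        return Tensor(batch)

    def forward(self, batch: np.ndarray) -> NetworkOutputs:
        """Inference forward pass (batch-norm in inference mode)."""
        x = self._to_tensor(batch)
        with no_grad():
            raw = self._forward(x, training=False)
        return NetworkOutputs(
            seg=raw["seg"].data[..., 0],
            boundary_aux={f: t.data[..., 0] for f, t in raw["boundary"].items()},
            edge_attn={f: t.data[..., 0] for f, t in raw["edge"].items()},
        )

    # ------------------------------------------------------- conveniences

    def fit(self, train_samples, val_samples, loss_weights=None,
            train_config=None, augment_config=None):
        """Train on samples; returns a TrainingResults object."""
        from .trainer import train
        return train(self, train_samples, val_samples,
                     loss_weights=loss_weights, config=train_config,
                     augment_config=augment_config)

    def predict(self, samples, threshold: float = 0.5,
                batch_size: int = 8) -> np.ndarray:
        from .trainer import predict_masks
        return predict_masks(self, samples, threshold=threshold,
                             batch_size=batch_size)

    def layer_table(self) -> list[tuple[str, str, tuple[int, ...]]]:
        """(name, type, output shape) per layer, from a traced forward."""
        s = self.config.input_size
        dummy = np.zeros((1, s, s, self.config.input_channels), np.float32)
        trace: list = []
        with no_grad():
            self._forward(Tensor(dummy), training=False, trace=trace)
        return trace

    def summary(self) -> str:
        rows = self.layer_table()
        lines = [f"{'Layer':<22} {'Type':<16} Output Shape",
                 "-" * 56]
        for name, kind, shape in rows:
            lines.append(f"{name:<22} {kind:<16} {shape}")
        lines.append("-" * 56)
        lines.append(f"Trainable parameters: {count_parameters(self):,}")
        return "\n".join(lines)

    # -------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint with the config embedded."""
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "EdgeAwareUNet":
        with np.load(path) as zf:
            state = {k: zf[k] for k in zf.files}
        cfg = ModelConfig(**json.loads(state.pop("__config__").tobytes()))
        model = cls(cfg)
        model.load_state_dict(state)
        return model


def build_model(config: ModelConfig | None = None, **kwargs) -> EdgeAwareUNet:
    """Construct the network for a configuration (or keyword overrides)."""
    return EdgeAwareUNet(config, **kwargs)


def count_parameters(model: EdgeAwareUNet) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))
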