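"""Trainable layers and the Adam optimizer for the segmentation network.

Layers hold their parameters as autodiff Tensors; a module tree exposes
``parameters()`` for the optimizer and ``state_dict``/``load_state_dict``
for checkpointing. Initialization is He (fan-in) normal from a
per-module RNG so builds are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, conv_transpose2x2, pad_edge1
from .edges import SOBEL_X, SOBEL_Y

__all__ = ["Module", "Conv2D", "ConvTranspose2D", "BatchNorm2D", "Adam",
           "sobel_magnitude_t", "channel_mean_t"]


class Module:
    """Base class: parameter discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.buffers(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{key}.{i}.")
            elif name.startswith("running_") and isinstance(val, np.ndarray):
                yield key, val

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buf:{k}": v.copy() for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, arr in state.items():
            if key.startswith("buf:"):
                bufs[key[4:]][...] = arr
            else:
                params[key].data[...] = arr


class Conv2D(Module):
    """3x3 (or 1x1) convolution, 'same' zero padding unless overridden."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None,
                 init_std: float | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * cin)) if init_std is None else init_std
        self.w = Tensor(rng.normal(0.0, std, (k, k, cin, cout)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.dilation = dilation
        self.padding = (k - 1) // 2 * dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, dilation=self.dilation,
                      padding=self.padding)


class ConvTranspose2D(Module):
    """Kernel-2 stride-2 transposed convolution (2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (4 * cin))
        self.w = Tensor(rng.normal(0.0, std, (2, 2, cin, cout)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.w, self.b)


class BatchNorm2D(Module):
    """Batch normalization over (N, H, W) per channel."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            inv = 1.0 / (var + self.eps).sqrt()
            return self.gamma * (xc * inv) + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - self.running_mean) * inv) + self.beta


def channel_mean_t(x: Tensor) -> Tensor:
    """Mean over the channel axis, keeping a singleton channel."""
    return x.mean(axis=3, keepdims=True)


def sobel_magnitude_t(x: Tensor) -> Tensor:
    """Differentiable per-channel Sobel magnitude, channel-averaged.

    Channels are folded into the batch so one single-channel fixed-kernel
    convolution serves any width; replicate padding matches the
    deterministic operator in :mod:`edgeunet.edges`.
    """
    n, h, w, c = x.shape
    xb = x.transpose(0, 3, 1, 2).reshape(n * c, h, w, 1)
    xp = pad_edge1(xb)
    kx = Tensor(SOBEL_X[:, :, None, None])
    ky = Tensor(SOBEL_Y[:, :, None, None])
    gx = conv2d(xp, kx)
    gy = conv2d(xp, ky)
    mag = (gx * gx + gy * gy + 1e-12).sqrt()
    mag = mag.reshape(n, c, h, w).transpose(0, 2, 3, 1)
    return channel_mean_t(mag)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
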