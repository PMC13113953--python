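"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network and its boundary-sensitive objective are trained
with gradient descent, so every building block here carries a closed-form
vector-Jacobian product. Arrays follow the NHWC layout ``(batch, height,
width, channels)`` and are kept in float32.

Only the operations the edge-aware U-Net needs are implemented: broadcast
arithmetic, matmul, 2-D convolution (stride/dilation via im2col), 2x2 max
pooling, stride-2 transposed convolution, replicate padding (for the Sobel
layers), pointwise nonlinearities and reductions. Gradient correctness is
guarded by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2",
    "pad_edge1",
]

_grad_enabled = [True]


class no_grad:
    """Context manager that disables graph construction (inference)."""

    def __enter__(self):
        self._prev = _grad_enabled[0]
        _grad_enabled[0] = False

    def __exit__(self, *exc):
        _grad_enabled[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # keep ndarray <op> Tensor from dispatching into NumPy elementwise
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def _needs_grad(self) -> bool:
        return _grad_enabled[0] and (self.requires_grad or bool(self._prev))

    def _accum(self, g: np.ndarray) -> None:
        if not self._needs_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float32), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p._needs_grad for p in prev):
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- pointwise ---------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self) -> "Tensor":
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data.astype(np.float64)))
        y = y.astype(np.float32)

        def bw(g):
            self._accum(g * y * (1.0 - y))

        return self._make(y, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)

        def bw(g):
            self._accum(g / (2.0 * np.maximum(y, 1e-12)))

        return self._make(y, (self,), bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through inside the range only."""
        inside = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis`` (channel fusion of skip connections)."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t._needs_grad for t in tensors):
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._prev = tuple(tensors)
        out._backward = bw
    return out


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation, NHWC input, ``(kh, kw, Cin, Cout)`` weights.

    Zero padding; im2col + matmul so the heavy lifting is a single BLAS
    call per layer.
    """
    kh, kw, cin, cout = w.data.shape
    if x.data.shape[3] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[3]}, weights expect {cin}"
        )
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0))) if p else x.data
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(1, 2))
    win = win[:, ::stride, ::stride, :, ::dilation, ::dilation]
    n, ho, wo = win.shape[:3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, kh * kw * cin
    )
    wmat = w.data.reshape(kh * kw * cin, cout)
    out_flat = cols @ wmat
    if b is not None:
        out_flat = out_flat + b.data
    out = Tensor(out_flat.reshape(n, ho, wo, cout))

    prev = (x, w) if b is None else (x, w, b)
    if any(t._needs_grad for t in prev):
        def bw(g):
            g_flat = g.reshape(n * ho * wo, cout)
            w._accum((cols.T @ g_flat).reshape(kh, kw, cin, cout))
            if b is not None:
                b._accum(g_flat.sum(axis=0))
            if x._needs_grad:
                dcols = (g_flat @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
                dxp = np.zeros(
                    (x.data.shape[0], x.data.shape[1] + 2 * p,
                     x.data.shape[2] + 2 * p, cin),
                    dtype=np.float32,
                )
                for a in range(kh):
                    ia = a * dilation
                    for c in range(kw):
                        ic = c * dilation
                        dxp[:, ia: ia + ho * stride: stride,
                            ic: ic + wo * stride: stride, :] += dcols[:, :, :, a, c, :]
                x._accum(dxp[:, p: dxp.shape[1] - p, p: dxp.shape[2] - p, :]
                         if p else dxp)

        out._prev = prev
        out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(h, w)}")
    blocks = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out_data = blocks.max(axis=(2, 4))
    out = Tensor(out_data)
    if x._needs_grad:
        winners = blocks == out_data[:, :, None, :, None, :]
        counts = winners.sum(axis=(2, 4), keepdims=True)

        def bw(g):
            gexp = g[:, :, None, :, None, :] * winners / counts
            x._accum(gexp.reshape(n, h, w, c))

        out._prev = (x,)
        out._backward = bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    Weights ``(2, 2, Cin, Cout)``; each input pixel expands into a 2x2
    output block, so output spatial dims are doubled.
    """
    n, h, wd, cin = x.data.shape
    _, _, wcin, cout = w.data.shape
    if cin != wcin:
        raise ValueError(f"channel mismatch: input has {cin}, weights expect {wcin}")
    y6 = np.tensordot(x.data, w.data, axes=([3], [2]))  # (N,H,W,2,2,O)
    y = np.ascontiguousarray(y6.transpose(0, 1, 3, 2, 4, 5)).reshape(
        n, 2 * h, 2 * wd, cout
    )
    if b is not None:
        y = y + b.data
    out = Tensor(y)
    prev = (x, w) if b is None else (x, w, b)
    if any(t._needs_grad for t in prev):
        def bw(g):
            g6 = g.reshape(n, h, 2, wd, 2, cout).transpose(0, 1, 3, 2, 4, 5)
            if b is not None:
                b._accum(g.sum(axis=(0, 1, 2)))
            dw = np.tensordot(x.data, g6, axes=([0, 1, 2], [0, 1, 2]))  # (C,2,2,O)
            w._accum(dw.transpose(1, 2, 0, 3))
            if x._needs_grad:
                x._accum(np.tensordot(g6, w.data, axes=([3, 4, 5], [0, 1, 3])))

        out._prev = prev
        out._backward = bw
    return out


def pad_edge1(x: Tensor) -> Tensor:
    """Replicate-pad spatial dims by one pixel (Sobel border handling)."""
    out = Tensor(np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge"))
    if x._needs_grad:
        def bw(g):
            dx = g[:, 1:-1, 1:-1, :].copy()
            dx[:, 0, :, :] += g[:, 0, 1:-1, :]
            dx[:, -1, :, :] += g[:, -1, 1:-1, :]
            dx[:, :, 0, :] += g[:, 1:-1, 0, :]
            dx[:, :, -1, :] += g[:, 1:-1, -1, :]
            dx[:, 0, 0, :] += g[:, 0, 0, :]
            dx[:, 0, -1, :] += g[:, 0, -1, :]
            dx[:, -1, 0, :] += g[:, -1, 0, :]
            dx[:, -1, -1, :] += g[:, -1, -1, :]
            x._accum(dx)

        out._prev = (x,)
        out._backward = bw
    return out
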