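"""Minimal numpy neural-network layer framework.

Provides exactly what the classifier module needs: declarative CNN
architectures with analytic shape/parameter/MAC accounting, inference forward
passes for the large backbones, and full backpropagation + Adam for the layers
the trainable small CNN uses. Arrays are NCHW float32.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "Linear", "ReLU", "MaxPool2d", "AvgPool2d",
    "AdaptiveAvgPool2d", "BatchNorm2d", "Dropout", "Flatten", "InputNorm",
    "Residual", "Sequential", "Adam", "UnsupportedLayerError",
]


class UnsupportedLayerError(TypeError):
    """A layer type the MAC counter does not know how to cost."""


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class Layer:
    """Base layer: forward/backward plus analytic accounting hooks.

    Setting ``frozen = True`` excludes a layer's weights from ``parameters()``
    (and hence from optimization and trainable-parameter counts)."""

    frozen: bool = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} has no backward pass")

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs of trainable arrays; empty when frozen."""
        return []

    def param_count(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape

    def macs(self, in_shape: tuple[int, ...]) -> int:
        """Multiply-accumulates for one sample; convolutions and affine layers
        only — bias, activations, pooling and normalization cost zero by the
        documented convention."""
        return 0


# ---------------------------------------------------------------------------
# im2col machinery shared by Conv2d

def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    shape = (n, c, kh, kw, oh, ow)
    strides = (
        xp.strides[0], xp.strides[1], xp.strides[2], xp.strides[3],
        xp.strides[2] * stride, xp.strides[3] * stride,
    )
    col = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    return np.ascontiguousarray(col).reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(dcol, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    dcol = dcol.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcol[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, rng=None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = _pair(kernel)
        self.stride, self.pad = stride, padding
        fan_in = in_ch * self.kh * self.kw
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((out_ch, in_ch, self.kh, self.kw)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def forward(self, x, train=False):
        col, oh, ow = _im2col(x, self.kh, self.kw, self.stride, self.pad)
        wmat = self.W.reshape(self.out_ch, -1)
        out = np.einsum("ok,nkp->nop", wmat, col)
        if self.b is not None:
            out += self.b[None, :, None]
        if train:
            self._cache = (x.shape, col)
        return out.reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, grad):
        x_shape, col = self._cache
        n, _, oh, ow = grad.shape[0], self.out_ch, *grad.shape[2:]
        g = grad.reshape(grad.shape[0], self.out_ch, -1)
        self.dW[...] = np.einsum("nop,nkp->ok", g, col).reshape(self.W.shape)
        if self.b is not None:
            self.db[...] = g.sum(axis=(0, 2))
        dcol = np.einsum("ok,nop->nkp", self.W.reshape(self.out_ch, -1), g)
        return _col2im(dcol, x_shape, self.kh, self.kw, self.stride, self.pad, oh, ow)

    def parameters(self):
        if self.frozen:
            return []
        out = [(self.W, self.dW)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out

    def out_shape(self, in_shape):
        c, h, w = in_shape
        oh = (h + 2 * self.pad - self.kh) // self.stride + 1
        ow = (w + 2 * self.pad - self.kw) // self.stride + 1
        return (self.out_ch, oh, ow)

    def macs(self, in_shape):
        _, oh, ow = self.out_shape(in_shape)
        return self.kh * self.kw * self.in_ch * self.out_ch * oh * ow


class Linear(Layer):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        self.in_f, self.out_f = in_f, out_f
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((out_f, in_f)) * np.sqrt(2.0 / in_f)).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        out = x @ self.W.T
        if self.b is not None:
            out += self.b
        return out

    def backward(self, grad):
        self.dW[...] = grad.T @ self._x
        if self.b is not None:
            self.db[...] = grad.sum(axis=0)
        return grad @ self.W

    def parameters(self):
        if self.frozen:
            return []
        out = [(self.W, self.dW)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out

    def out_shape(self, in_shape):
        return (self.out_f,)

    def macs(self, in_shape):
        return self.in_f * self.out_f


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel, stride=None):
        self.k = kernel
        self.stride = stride or kernel

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        oh, ow = (h - k) // s + 1, (w - k) // s + 1
        col, _, _ = _im2col(x.reshape(n * c, 1, h, w), k, k, s, 0)
        col = col.reshape(n * c, k * k, oh * ow)
        idx = col.argmax(axis=1)
        out = np.take_along_axis(col, idx[:, None, :], axis=1)[:, 0, :]
        if train:
            self._cache = (x.shape, idx, oh, ow)
        return out.reshape(n, c, oh, ow)

    def backward(self, grad):
        x_shape, idx, oh, ow = self._cache
        n, c, h, w = x_shape
        k, s = self.k, self.stride
        dcol = np.zeros((n * c, k * k, oh * ow), dtype=grad.dtype)
        g = grad.reshape(n * c, 1, oh * ow)
        np.put_along_axis(dcol, idx[:, None, :], g, axis=1)
        dx = _col2im(dcol, (n * c, 1, h, w), k, k, s, 0, oh, ow)
        return dx.reshape(n, c, h, w)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1)


class AvgPool2d(Layer):
    def __init__(self, kernel, stride=None):
        self.k = kernel
        self.stride = stride or kernel

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        oh, ow = (h - k) // s + 1, (w - k) // s + 1
        if train:
            self._x_shape = x.shape
        view = x[:, :, : oh * s, : ow * s].reshape(n, c, oh, s, ow, s)[:, :, :, :k, :, :k]
        return view.mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._x_shape
        k, s = self.k, self.stride
        oh, ow = grad.shape[2], grad.shape[3]
        dx = np.zeros(self._x_shape, dtype=grad.dtype)
        g = grad / (k * k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += g
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1)


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output size (inference only)."""

    def __init__(self, out_hw):
        self.oh, self.ow = _pair(out_hw)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        out = np.empty((n, c, self.oh, self.ow), dtype=x.dtype)
        hb = np.linspace(0, h, self.oh + 1).astype(int)
        wb = np.linspace(0, w, self.ow + 1).astype(int)
        for i in range(self.oh):
            for j in range(self.ow):
                out[:, :, i, j] = x[:, :, hb[i]:hb[i + 1], wb[j]:wb[j + 1]].mean(axis=(2, 3))
        return out

    def out_shape(self, in_shape):
        return (in_shape[0], self.oh, self.ow)


class BatchNorm2d(Layer):
    """Batch normalization, inference mode (running statistics)."""

    def __init__(self, ch):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.eps = 1e-5

    def forward(self, x, train=False):
        inv = self.gamma / np.sqrt(self.running_var + self.eps)
        return x * inv[None, :, None, None] + (self.beta - self.running_mean * inv)[None, :, None, None]

    def parameters(self):
        if self.frozen:
            return []
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class InputNorm(Layer):
    """Per-sample standardization over all input elements.

    Spectrogram tensors are dominated by a large constant background after the
    fixed channel standardization; removing each sample's mean/scale here keeps
    the first convolution's activations well conditioned. Treated as fixed
    preprocessing in the backward pass."""

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True) + 1e-6
        return (x - mu) / sd

    def backward(self, grad):
        return grad


class Dropout(Layer):
    def __init__(self, p=0.5):
        if not (0 <= p < 1):
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0:
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Residual(Layer):
    """Residual block: out = relu(main(x) + shortcut(x)); inference only."""

    def __init__(self, main: "Sequential", shortcut: "Sequential | None" = None):
        self.main = main
        self.shortcut = shortcut

    def forward(self, x, train=False):
        idn = self.shortcut.forward(x, train) if self.shortcut else x
        return np.maximum(self.main.forward(x, train) + idn, 0)

    def parameters(self):
        if self.frozen:
            return []
        out = self.main.parameters()
        if self.shortcut:
            out += self.shortcut.parameters()
        return out

    def out_shape(self, in_shape):
        return self.main.out_shape(in_shape)

    def macs(self, in_shape):
        total = self.main.macs(in_shape)
        if self.shortcut:
            total += self.shortcut.macs(in_shape)
        return total


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        if self.frozen:
            return []
        return [pg for layer in self.layers for pg in layer.parameters()]

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def macs(self, in_shape):
        total = 0
        for layer in self.layers:
            total += _layer_macs(layer, in_shape)
            in_shape = layer.out_shape(in_shape)
        return total


_COSTED = (Conv2d, Linear, Sequential, Residual)
_ZERO_COST = (ReLU, MaxPool2d, AvgPool2d, AdaptiveAvgPool2d, BatchNorm2d, Dropout, Flatten, InputNorm)


def _layer_macs(layer: Layer, in_shape) -> int:
    if isinstance(layer, _COSTED):
        return layer.macs(in_shape)
    if isinstance(layer, _ZERO_COST):
        return 0
    raise UnsupportedLayerError(f"cannot cost layer type {type(layer).__name__}")


class Adam:
    """Adam optimizer over (param, grad) pairs updated in place."""

    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
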