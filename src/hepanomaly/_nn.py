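"""Minimal numpy neural-network toolkit used by the diffusion and reconstruction models.

Implements exactly the pieces the pipeline needs — 2-D convolution,
transposed convolution, batch normalisation, ReLU, dropout, linear layers,
an Adam optimiser and EMA weight tracking — with hand-written reverse-mode
gradients. Convolutions are evaluated as im2col + BLAS matmul, which is the
fastest pure-numpy route at the 64–512 px slice sizes this package targets.

All layers follow a tiny protocol: ``forward(x, train)`` caches what the
backward pass needs, ``backward(gy)`` returns the input gradient and fills
``grads`` (same keys as ``params``). Gradients are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "Linear",
    "Sequential",
    "Adam",
    "collect_params",
    "get_state",
    "set_state",
    "ema_update",
]


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Return windows of shape (N, C, Ho, Wo, k, k) as a strided view."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d_forward(x, W, stride, pad):
    """y[n,o] = sum_c W[o,c] * x[n,c] (cross-correlation). Returns (y, cols)."""
    cols = _im2col(x, W.shape[2], stride, pad)
    y = np.tensordot(cols, W, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,O)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)), cols


def conv2d_backward_weight(cols, gy):
    # cols (N,C,Ho,Wo,k,k), gy (N,O,Ho,Wo) -> dW (O,C,k,k)
    return np.tensordot(gy, cols, axes=([0, 2, 3], [0, 2, 3]))


def conv2d_backward_data(gy, W, stride, pad, x_shape):
    """Adjoint of conv2d_forward with respect to its input."""
    N, C, H, Wd = x_shape
    k = W.shape[2]
    dcols = np.tensordot(gy, W, axes=([1], [0]))  # (N,Ho,Wo,C,k,k)
    dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N,C,Ho,Wo,k,k)
    Ho, Wo = dcols.shape[2], dcols.shape[3]
    dxp = np.zeros((N, C, H + 2 * pad, Wd + 2 * pad), dtype=gy.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dcols[:, :, :, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv_out(n, k, stride, pad):
    return (n + 2 * pad - k) // stride + 1


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class; layers without parameters leave ``params`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (cin * k * k))
        self.params["W"] = (rng.standard_normal((cout, cin, k, k)) * scale).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.stride, self.pad = stride, pad

    def forward(self, x, train=True):
        y, cols = conv2d_forward(x, self.params["W"], self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        return y + self.params["b"][None, :, None, None]

    def backward(self, gy):
        self.grads["W"] = conv2d_backward_weight(self._cols, gy)
        self.grads["b"] = gy.sum((0, 2, 3))
        dx = conv2d_backward_data(gy, self.params["W"], self.stride, self.pad, self._x_shape)
        self._cols = None
        return dx


class ConvTranspose2d(Layer):
    """Stride-2 upsampling as the exact adjoint of a stride-2 convolution.

    Output spatial size is ``stride * input size`` (k=3, pad=1 convention).
    """

    def __init__(self, cin, cout, k=3, stride=2, pad=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (cin * k * k))
        # stored in conv layout: (conv-out, conv-in) = (cin, cout)
        self.params["W"] = (rng.standard_normal((cin, cout, k, k)) * scale).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=True):
        N, C, H, Wd = x.shape
        out_hw = (H * self.stride, Wd * self.stride)
        if _conv_out(out_hw[0], self.k, self.stride, self.pad) != H:
            raise ValueError("incompatible transposed-conv geometry")
        self._x = x
        y = conv2d_backward_data(x, self.params["W"], self.stride, self.pad,
                                 (N, self.params["W"].shape[1], *out_hw))
        return y + self.params["b"][None, :, None, None]

    def backward(self, gy):
        cols = _im2col(gy, self.k, self.stride, self.pad)
        self.grads["W"] = conv2d_backward_weight(cols, self._x)
        self.grads["b"] = gy.sum((0, 2, 3))
        dx = np.tensordot(cols, self.params["W"], axes=([1, 4, 5], [1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    def __init__(self, c, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x, train=True):
        if train:
            mean = x.mean((0, 2, 3))
            var = x.var((0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, gy):
        xhat, invstd, train = self._cache
        self.grads["gamma"] = (gy * xhat).sum((0, 2, 3))
        self.grads["beta"] = gy.sum((0, 2, 3))
        g = gy * self.params["gamma"][None, :, None, None]
        if not train:
            return g * invstd[None, :, None, None]
        M = gy.shape[0] * gy.shape[2] * gy.shape[3]
        sum_g = g.sum((0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum((0, 2, 3), keepdims=True)
        dx = (g - sum_g / M - xhat * sum_gx / M) * invstd[None, :, None, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout(Layer):
    def __init__(self, p, rng=None):
        super().__init__()
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Linear(Layer):
    def __init__(self, din, dout, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / din)
        self.params["W"] = (rng.standard_normal((din, dout)) * scale).astype(dtype)
        self.params["b"] = np.zeros(dout, dtype=dtype)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(0)
        dx = gy @ self.params["W"].T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


# ---------------------------------------------------------------------------
# parameter bookkeeping, optimiser, EMA
# ---------------------------------------------------------------------------

def collect_layers(model, prefix=""):
    """Yield (path, layer) for every leaf layer reachable from model.

    A model is any object with a ``layers_dict()`` method returning
    {name: Layer}, or a Sequential/Layer itself.
    """
    if isinstance(model, Sequential):
        items = [(str(i), l) for i, l in enumerate(model.layers)]
    elif isinstance(model, Layer):
        items = [("", model)]
    else:
        items = list(model.layers_dict().items())
    out = []
    for name, layer in items:
        path = f"{prefix}{name}" if name else prefix.rstrip(".")
        if isinstance(layer, Sequential):
            out.extend(collect_layers(layer, prefix=f"{path}."))
        else:
            out.append((path, layer))
    return out


def collect_params(model):
    """Yield (path, layer, key) for every parameter array reachable from model."""
    out = []
    for path, layer in collect_layers(model):
        for key in layer.params:
            out.append((f"{path}.{key}" if path else key, layer, key))
    return out


def get_state(model):
    """Copy all parameters plus BatchNorm running statistics into a flat dict."""
    state = {path: layer.params[key].copy() for path, layer, key in collect_params(model)}
    for path, layer in collect_layers(model):
        if isinstance(layer, BatchNorm2d):
            state[f"{path}:running_mean"] = layer.running_mean.copy()
            state[f"{path}:running_var"] = layer.running_var.copy()
    return state


def set_state(model, state):
    for path, layer, key in collect_params(model):
        layer.params[key] = state[path].copy()
    for path, layer in collect_layers(model):
        if isinstance(layer, BatchNorm2d):
            layer.running_mean = state[f"{path}:running_mean"].copy()
            layer.running_var = state[f"{path}:running_var"].copy()


def ema_update(ema_weights, model_weights, momentum):
    """ema <- momentum * ema + (1 - momentum) * model, elementwise, in place.

    Both arguments are {path: array} dicts with matching keys and shapes.
    """
    if set(ema_weights) != set(model_weights):
        raise ValueError("EMA/model parameter sets differ")
    for key, w in model_weights.items():
        e = ema_weights[key]
        if e.shape != w.shape:
            raise ValueError(f"shape mismatch for {key}: {e.shape} vs {w.shape}")
        e *= momentum
        e += (1.0 - momentum) * w
    return ema_weights


class Adam:
    def __init__(self, model, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = collect_params(model)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {p: np.zeros_like(l.params[k]) for p, l, k in self.entries}
        self.v = {p: np.zeros_like(l.params[k]) for p, l, k in self.entries}

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for path, layer, key in self.entries:
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self.m[path]
            v = self.v[path]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            layer.params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for _, layer, key in self.entries:
            layer.grads.pop(key, None)
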