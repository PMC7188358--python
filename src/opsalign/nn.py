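"""Minimal numpy layer engine for compact EEG conv-nets.

Implements exactly the layer vocabulary the two decoder architectures need —
unit-stride (optionally grouped) 2-D convolution, batch normalization,
square/log/ELU activations, 1-D average pooling along time, dropout and a
linear head — with hand-derived backward passes and an Adam optimizer.
Everything runs on CPU; the networks involved are small (a few thousand
parameters, 3 x 300 inputs) so im2col-style windowing with einsum is fast
enough for full training runs.

Conventions: tensors are (batch, channels, height, width) float64; ``rng``
(a numpy Generator) drives dropout masks; layers accumulate gradients in
``grads`` aligned with ``params``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "Square",
    "LogClip",
    "ELU",
    "AvgPool1dTime",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "softmax",
    "cross_entropy",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train: bool, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _channel_major_cols(x, kh, kw):
    """im2col: (B, C, H, W) -> contiguous (B, C*kh*kw, H_out*W_out)."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B, C, Ho, Wo, kh, kw)
    b, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(b, c * kh * kw, ho * wo), (ho, wo)


class Conv2d(Layer):
    """Grouped 2-D convolution, stride 1 (pooling layers handle striding).

    ``first_layer=True`` skips the input-gradient computation (nothing below
    the first layer needs it), roughly halving its backward cost.
    """

    def __init__(self, in_ch, out_ch, kernel, padding=(0, 0), groups=1, rng=None,
                 first_layer=False, dtype=np.float64):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channel counts must divide by groups")
        self.in_ch, self.out_ch, self.groups = in_ch, out_ch, groups
        self.kh, self.kw = kernel
        self.ph, self.pw = padding
        self.first_layer = first_layer
        cg = in_ch // groups
        fan_in = cg * self.kh * self.kw
        fan_out = (out_ch // groups) * self.kh * self.kw
        rng = rng or np.random.default_rng()
        self.W = glorot_uniform(rng, (out_ch, cg, self.kh, self.kw), fan_in, fan_out, dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        self._x_shape = x.shape
        cols, (ho, wo) = _channel_major_cols(xp, self.kh, self.kw)
        self._cols = cols
        og = self.out_ch // self.groups
        kg = (self.in_ch // self.groups) * self.kh * self.kw
        outs = []
        for g in range(self.groups):
            w2 = self.W[g * og : (g + 1) * og].reshape(og, kg)
            outs.append(w2 @ cols[:, g * kg : (g + 1) * kg])
        out = np.concatenate(outs, axis=1).reshape(x.shape[0], self.out_ch, ho, wo)
        return out + self.b[None, :, None, None]

    def backward(self, grad):
        b = grad.shape[0]
        og = self.out_ch // self.groups
        cg = self.in_ch // self.groups
        kg = cg * self.kh * self.kw
        self.grads[1][:] = grad.sum(axis=(0, 2, 3))
        g2 = np.ascontiguousarray(grad.reshape(b, self.out_ch, -1))
        for g in range(self.groups):
            go = g2[:, g * og : (g + 1) * og]
            dW = np.tensordot(go, self._cols[:, g * kg : (g + 1) * kg], axes=([0, 2], [0, 2]))
            self.grads[0][g * og : (g + 1) * og] = dW.reshape(og, cg, self.kh, self.kw)
        self._cols = None
        if self.first_layer:
            return None
        # input gradient = full correlation of the padded output gradient
        # with the spatially flipped kernel
        gp = np.pad(
            grad,
            (
                (0, 0),
                (0, 0),
                (self.kh - 1 - self.ph, self.kh - 1 - self.ph),
                (self.kw - 1 - self.pw, self.kw - 1 - self.pw),
            ),
        )
        gcols, _ = _channel_major_cols(gp, self.kh, self.kw)
        Wf = np.ascontiguousarray(self.W[:, :, ::-1, ::-1])
        okg = og * self.kh * self.kw
        dxs = []
        for g in range(self.groups):
            wf2 = np.ascontiguousarray(
                Wf[g * og : (g + 1) * og].transpose(1, 0, 2, 3)
            ).reshape(cg, okg)
            dxs.append(wf2 @ gcols[:, g * okg : (g + 1) * okg])
        h, w = self._x_shape[2], self._x_shape[3]
        return np.concatenate(dxs, axis=1).reshape(b, self.in_ch, h, w)

    def out_shape(self, in_shape):
        return (
            self.out_ch,
            in_shape[1] + 2 * self.ph - self.kh + 1,
            in_shape[2] + 2 * self.pw - self.kw + 1,
        )


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, n_ch, eps=1e-5, momentum=0.1, dtype=np.float64):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma, self.beta = np.ones(n_ch, dtype=dtype), np.zeros(n_ch, dtype=dtype)
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros(n_ch, dtype=dtype), np.zeros(n_ch, dtype=dtype)]

    def forward(self, x, train, rng):
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=x.dtype)
            var = x.var(axis=(0, 2, 3), dtype=x.dtype)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.grads[0][:] = (grad * xhat).sum(axis=(0, 2, 3))
        self.grads[1][:] = grad.sum(axis=(0, 2, 3))
        gxh = grad * self.gamma[None, :, None, None]
        if not self._train:
            return gxh / std[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = gxh.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (gxh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (gxh - sum_g / n - xhat * sum_gx / n) / std[None, :, None, None]

    def out_shape(self, in_shape):
        return in_shape


class Square(Layer):
    def forward(self, x, train, rng):
        self._x = x
        return x * x

    def backward(self, grad):
        return 2.0 * self._x * grad

    def out_shape(self, in_shape):
        return in_shape


class LogClip(Layer):
    """Elementwise log with a small floor so zero inputs stay finite."""

    def __init__(self, floor=1e-6):
        super().__init__()
        self.floor = floor

    def forward(self, x, train, rng):
        self._clipped = np.maximum(x, self.floor)
        self._mask = x > self.floor
        return np.log(self._clipped)

    def backward(self, grad):
        return grad * self._mask / self._clipped

    def out_shape(self, in_shape):
        return in_shape


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._neg = x < 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0)
        return np.where(self._neg, self.alpha * self._expm1, x)

    def backward(self, grad):
        return grad * np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0)

    def out_shape(self, in_shape):
        return in_shape


class AvgPool1dTime(Layer):
    """Average pooling along the time (last) axis with kernel kw, stride sw."""

    def __init__(self, kw, sw):
        super().__init__()
        self.kw, self.sw = kw, sw

    def forward(self, x, train, rng):
        self._in_w = x.shape[3]
        wins = sliding_window_view(x, self.kw, axis=3)[:, :, :, :: self.sw, :]
        return wins.mean(axis=-1)

    def backward(self, grad):
        b, c, h, n_out = grad.shape
        dx = np.zeros((b, c, h, self._in_w), dtype=grad.dtype)
        g = grad / self.kw
        for j in range(n_out):  # n_out <= ~75, cheap
            dx[:, :, :, j * self.sw : j * self.sw + self.kw] += g[:, :, :, j : j + 1]
        return dx

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, h, (w - self.kw) // self.sw + 1)


class Dropout(Layer):
    def __init__(self, p=0.5):
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][:] = self._x.T @ grad
        self.grads[1][:] = grad.sum(axis=0)
        return grad @ self.W.T

    def out_shape(self, in_shape):
        return (self.b.shape[0],)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def state(self):
        """Deep copy of all learnable and running state (for best-epoch restore)."""
        extra = []
        for l in self.layers:
            if isinstance(l, BatchNorm2d):
                extra.append((l.running_mean.copy(), l.running_var.copy()))
        return [p.copy() for p in self.params], extra

    def load_state(self, state):
        params, extra = state
        for p, saved in zip(self.params, params):
            p[:] = saved
        bns = [l for l in self.layers if isinstance(l, BatchNorm2d)]
        for l, (rm, rv) in zip(bns, extra):
            l.running_mean[:] = rm
            l.running_var[:] = rv

    def shape_trace(self, in_shape):
        """Intermediate (channels, height, width) shapes after every layer."""
        shapes = [in_shape]
        for l in self.layers:
            shapes.append(l.out_shape(shapes[-1]))
        return shapes


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean softmax cross-entropy and its gradient wrt logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params, grads, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
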