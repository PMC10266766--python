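"""Minimal seeded neural-network framework (numpy, manual backprop).

Implements exactly the pieces the stability models need — 3D convolution
with 'same' padding, batch normalization, leaky ReLU, 2x max pooling, dense
layers, softmax cross-entropy and MAE-through-sigmoid losses, and the Adam
optimizer.  Everything is deterministic given the construction seed: two
models built with the same seed have bitwise-identical parameters, and
training with the same data order reproduces identical histories.

Array convention: conv inputs are (batch, channels, D, H, W); dense inputs
are (batch, features).  Gradients are exact (verified by central-difference
checks in the test suite), with max-pool ties sharing gradient equally.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param((rng.standard_normal((n_in, n_out)) * scale).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Conv3d(Layer):
    """3D convolution, kernel k x k x k, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel edge must be odd for 'same' padding")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k ** 3))
        self.W = Param((rng.standard_normal((c_out, c_in, k, k, k)) * scale
                        ).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        # correlation as a sum of k^3 shifted batched matmuls over channels:
        # y[b,f,:] = sum_off W[f,:,off] @ xp_shifted[b,:,:]  (BLAS-friendly,
        # avoids materializing the full im2col matrix)
        b, c, d, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp, self._shape = xp, (b, c, d, h, w)
        n = d * h * w
        acc = np.zeros((b, self.c_out, n), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(
                        xp[:, :, i:i + d, j:j + h, l:l + w]).reshape(b, c, n)
                    acc += np.matmul(self.W.value[:, :, i, j, l], xs)
        acc += self.b.value[:, None]
        return acc.reshape(b, self.c_out, d, h, w)

    def backward(self, dout):
        b, c, d, h, w = self._shape
        k, p = self.k, self.k // 2
        n = d * h * w
        df = np.ascontiguousarray(dout).reshape(b, self.c_out, n)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(
                        self._xp[:, :, i:i + d, j:j + h, l:l + w]
                        ).reshape(b, c, n)
                    self.W.grad[:, :, i, j, l] += np.matmul(
                        df, xs.transpose(0, 2, 1)).sum(axis=0)
                    dxs = np.matmul(self.W.value[:, :, i, j, l].T, df)
                    dxp[:, :, i:i + d, j:j + h, l:l + w] += \
                        dxs.reshape(b, c, d, h, w)
        self.b.grad += df.sum(axis=(0, 2))
        return dxp[:, :, p:-p, p:-p, p:-p] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for conv input)."""

    def __init__(self, n_channels: int, spatial: bool, dtype=np.float32,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels, dtype=dtype))
        self.beta = Param(np.zeros(n_channels, dtype=dtype))
        self.spatial = spatial
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def _axes_shape(self, x):
        if self.spatial:
            return (0, 2, 3, 4), (1, -1, 1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x):
        axes, shape = self._axes_shape(x)
        if self.train_mode:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._xhat, self._std, self._shape_b = xhat, std, shape
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout):
        axes, shape = self._axes_shape(dout)
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        if not self.train_mode:
            return dxhat / std.reshape(shape)
        m = dout.size / dout.shape[1] if self.spatial else dout.shape[0]
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std.reshape(shape)

    def state(self):
        return [self.running_mean.copy(), self.running_var.copy()]

    def load_state(self, s):
        self.running_mean, self.running_var = s[0].copy(), s[1].copy()


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool3d(Layer):
    """Non-overlapping pooling with edge ``e``; trailing voxels that do not
    fill a window are dropped (floor semantics)."""

    def __init__(self, e: int = 2):
        self.e = e

    def forward(self, x):
        e = self.e
        b, c, d, h, w = x.shape
        dd, hh, ww = d // e, h // e, w // e
        self._in_shape = x.shape
        xc = x[:, :, :dd * e, :hh * e, :ww * e]
        xr = xc.reshape(b, c, dd, e, hh, e, ww, e)
        out = xr.max(axis=(3, 5, 7))
        mask = (xr == out[:, :, :, None, :, None, :, None])
        self._mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)
        return out

    def backward(self, dout):
        b, c, d, h, w = self._in_shape
        e = self.e
        dxr = self._mask * dout[:, :, :, None, :, None, :, None]
        dd, hh, ww = d // e, h // e, w // e
        dxc = dxr.reshape(b, c, dd * e, hh * e, ww * e)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, :dd * e, :hh * e, :ww * e] = dxc
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for lyr in self.layers for p in lyr.params()]

    def set_mode(self, train: bool) -> None:
        for lyr in self.layers:
            lyr.train_mode = train

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.set_mode(train)
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- checkpointing -----------------------------------------------------
    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                arrays.extend(lyr.state())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        n = len(self.params())
        for p, a in zip(self.params(), arrays[:n]):
            p.value = a.copy()
        i = n
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                lyr.load_state(arrays[i:i + 2])
                i += 2


class Adam:
    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                        ).astype(p.value.dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(logits.dtype)


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error; returns (loss, dpred)."""
    r = pred - target
    return float(np.abs(r).mean()), (np.sign(r) / r.size).astype(pred.dtype)
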