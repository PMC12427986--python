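"""Minimal 1-D convolutional network engine (numpy, explicit backprop).

Implements exactly the layers the three classifier architectures need:
length-preserving 1-D convolution, batch normalization, ReLU, max-pooling
by an integer factor, transposed convolution with kernel == stride
(exact x4 upsampling), depthwise and pointwise convolutions, a
squeeze-and-excitation gate, global average pooling and a dense head with
softmax cross-entropy.  Data layout is (batch, length, channels)
throughout.  All randomness flows through an explicit numpy Generator so
training is reproducible bit-for-bit on one platform.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot_uniform(
    rng: np.random.Generator, shape, fan_in: int, fan_out: int
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1DSame(Layer):
    """k-tap 1-D convolution, zero-padded to preserve length."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        self.w = Param(_glorot_uniform(rng, (k, cin, cout), k * cin, k * cout))
        self.b = Param(np.zeros(cout))
        self.pl = (k - 1) // 2
        self.pr = k - 1 - self.pl

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        n, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pl, self.pr), (0, 0)))
        self._xp, self._L = xp, L
        y = np.zeros((n, L, self.w.value.shape[2]))
        for m in range(self.k):
            y += xp[:, m : m + L, :] @ self.w.value[m]
        return y + self.b.value

    def backward(self, dy):
        L = self._L
        dxp = np.zeros_like(self._xp)
        for m in range(self.k):
            self.w.grad[m] += np.einsum("nlc,nlo->co", self._xp[:, m : m + L, :], dy)
            dxp[:, m : m + L, :] += dy @ self.w.value[m].T
        self.b.grad += dy.sum(axis=(0, 1))
        return dxp[:, self.pl : self.pl + L, :]


class PointwiseConv1D(Layer):
    """1x1 convolution: a dense map applied at every position."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(_glorot_uniform(rng, (cin, cout), cin, cout))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += np.einsum("nlc,nlo->co", self._x, dy)
        self.b.grad += dy.sum(axis=(0, 1))
        return dy @ self.w.value.T


class DepthwiseConv1D(Layer):
    """Per-channel k-tap convolution (no cross-channel mixing), pad 1."""

    def __init__(self, channels: int, k: int, stride: int, rng: np.random.Generator):
        self.k, self.stride = k, stride
        self.w = Param(_glorot_uniform(rng, (k, channels), k, k))
        self.b = Param(np.zeros(channels))

    def params(self):
        return [self.w, self.b]

    def out_length(self, L: int) -> int:
        return (L + 2 * ((self.k - 1) // 2) - self.k) // self.stride + 1

    def forward(self, x, train):
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        Lo = self.out_length(x.shape[1])
        self._xp, self._Lin = xp, x.shape[1]
        y = np.zeros((x.shape[0], Lo, x.shape[2]))
        for m in range(self.k):
            y += xp[:, m : m + self.stride * Lo : self.stride, :] * self.w.value[m]
        return y + self.b.value

    def backward(self, dy):
        p = (self.k - 1) // 2
        Lo = dy.shape[1]
        dxp = np.zeros_like(self._xp)
        for m in range(self.k):
            sl = slice(m, m + self.stride * Lo, self.stride)
            self.w.grad[m] += np.einsum("nlc,nlc->c", self._xp[:, sl, :], dy)
            dxp[:, sl, :] += dy * self.w.value[m]
        self.b.grad += dy.sum(axis=(0, 1))
        return dxp[:, p : p + self._Lin, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * inv
        self._xhat, self._inv, self._N = xhat, inv, x.shape[0] * x.shape[1]
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, N = self._xhat, self._inv, self._N
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        return (inv / N) * (
            N * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Max-pool by an integer factor with floor truncation of the tail."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train):
        n, L, c = x.shape
        Lo = L // self.factor
        xr = x[:, : Lo * self.factor, :].reshape(n, Lo, self.factor, c)
        self._idx = xr.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, L, c = self._shape
        Lo = dy.shape[1]
        dxr = np.zeros((n, Lo, self.factor, c))
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, L, c))
        dx[:, : Lo * self.factor, :] = dxr.reshape(n, Lo * self.factor, c)
        return dx


class ConvTranspose1D(Layer):
    """Transposed convolution with kernel == stride: exact integer upsampling."""

    def __init__(self, cin: int, cout: int, factor: int, rng: np.random.Generator):
        self.factor = factor
        self.w = Param(_glorot_uniform(rng, (cin, factor, cout), factor * cin, factor * cout))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        n, L, _ = x.shape
        cout = self.w.value.shape[2]
        y = np.einsum("nlc,cko->nlko", x, self.w.value).reshape(
            n, L * self.factor, cout
        )
        return y + self.b.value

    def backward(self, dy):
        n, Lf, cout = dy.shape
        dyr = dy.reshape(n, Lf // self.factor, self.factor, cout)
        self.w.grad += np.einsum("nlc,nlko->cko", self._x, dyr)
        self.b.grad += dy.sum(axis=(0, 1))
        return np.einsum("nlko,cko->nlc", dyr, self.w.value)


class GlobalAvgPool1D(Layer):
    def forward(self, x, train):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.w = Param(_glorot_uniform(rng, (fin, fout), fin, fout))
        self.b = Param(np.zeros(fout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class SEBlock(Layer):
    """Squeeze-and-excitation: channel gate from globally pooled features."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, train):
        self._x = x
        s = x.mean(axis=1)
        z = self.fc1.forward(s, train)
        self._zmask = z > 0
        h = z * self._zmask
        g = 1.0 / (1.0 + np.exp(-self.fc2.forward(h, train)))
        self._g = g
        return x * g[:, None, :]

    def backward(self, dy):
        x, g = self._x, self._g
        dx = dy * g[:, None, :]
        dg = (dy * x).sum(axis=1)
        dh = self.fc2.backward(dg * g * (1.0 - g))
        ds = self.fc1.backward(dh * self._zmask)
        return dx + ds[:, None, :] / x.shape[1]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def conv_bn_relu(cin: int, cout: int, k: int, rng: np.random.Generator) -> Sequential:
    return Sequential(Conv1DSame(cin, cout, k, rng), BatchNorm1D(cout), ReLU())


def center_crop(x: np.ndarray, target_len: int) -> tuple[np.ndarray, int]:
    """Center-crop along length; returns (cropped, start offset)."""
    start = (x.shape[1] - target_len) // 2
    return x[:, start : start + target_len, :], start


class InvertedResidual(Layer):
    """Expand -> depthwise -> SE -> linear project, with residual when shapes match."""

    def __init__(
        self,
        cin: int,
        cout: int,
        stride: int,
        rng: np.random.Generator,
        expansion: int = 4,
        k: int = 3,
        se_reduction: int = 4,
    ):
        mid = cin * expansion
        self.stride, self.cin, self.cout = stride, cin, cout
        self.expand = Sequential(PointwiseConv1D(cin, mid, rng), BatchNorm1D(mid), ReLU())
        self.depthwise = DepthwiseConv1D(mid, k, stride, rng)
        self.dw_bn_relu = Sequential(BatchNorm1D(mid), ReLU())
        self.se = SEBlock(mid, se_reduction, rng)
        self.project = Sequential(PointwiseConv1D(mid, cout, rng), BatchNorm1D(cout))
        self.use_residual = stride == 1 and cin == cout

    def params(self):
        return (
            self.expand.params()
            + self.depthwise.params()
            + self.dw_bn_relu.params()
            + self.se.params()
            + self.project.params()
        )

    def forward(self, x, train):
        y = self.expand.forward(x, train)
        y = self.depthwise.forward(y, train)
        y = self.dw_bn_relu.forward(y, train)
        y = self.se.forward(y, train)
        y = self.project.forward(y, train)
        return y + x if self.use_residual else y

    def backward(self, dy):
        dx = self.project.backward(dy)
        dx = self.se.backward(dx)
        dx = self.dw_bn_relu.backward(dx)
        dx = self.depthwise.backward(dx)
        dx = self.expand.backward(dx)
        return dx + dy if self.use_residual else dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def count_parameters(layer: Layer) -> int:
    return sum(p.value.size for p in layer.params())
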