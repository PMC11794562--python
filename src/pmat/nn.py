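"""Minimal CPU neural-network layers on numpy.

Implements exactly what the heartbeat classifier needs: 2-D convolution
(im2col + GEMM), batch normalization, ReLU, non-overlapping max pooling,
global (adaptive 1x1) max pooling, dense layers, a fused softmax
cross-entropy loss and the Adam optimizer.  Every layer exposes
``forward``/``backward`` and lists its trainable parameters; gradients are
verified against finite differences in the test suite.

Conventions: activations are ``(N, C, H, W)`` float32 for image layers and
``(N, F)`` for dense layers; layers cache what backward needs.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays needed to restore the layer (params + running stats)."""
        return [p.value for p in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays, strict=True):
            p.value[...] = a

    def output_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution, square kernel, no padding, stride 1.

    ``compute_dx=False`` skips the input gradient (valid for the first
    layer of a network).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, compute_dx: bool = True):
        self.in_c = in_channels
        self.out_c = out_channels
        self.k = kernel_size
        self.compute_dx = compute_dx
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel_size, kernel_size))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def output_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_c:
            raise ValueError(f"Conv2D expects {self.in_c} channels, got {c}")
        return (self.out_c, h - self.k + 1, w - self.k + 1)

    def forward(self, x, training):
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        # im2col in (N, C, k*k, Ho, Wo) layout: k*k strided copies, no
        # 6-D transpose (the naive layout dominates runtime otherwise)
        cols = np.empty((n, c, k * k, ho, wo), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, ki * k + kj] = x[:, :, ki:ki + ho, kj:kj + wo]
        cols = cols.reshape(n, c * k * k, ho * wo)
        self._cols = cols
        self._x_shape = x.shape
        w2 = self.W.value.reshape(self.out_c, -1)
        out = np.matmul(w2, cols)  # (N, out_c, Ho*Wo)
        out += self.b.value[None, :, None]
        return out.reshape(n, self.out_c, ho, wo)

    def backward(self, dout):
        n, oc, ho, wo = dout.shape
        k = self.k
        ckk = self.in_c * k * k
        # single large GEMMs beat batched matmul here: fold the batch into
        # the free dimension
        dT = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(oc, -1)
        colsT = np.ascontiguousarray(
            self._cols.transpose(1, 0, 2)).reshape(ckk, -1)
        self.W.grad[...] = (dT @ colsT.T).reshape(self.W.value.shape)
        self.b.grad[...] = dT.sum(axis=1)
        if not self.compute_dx:
            return None
        w2 = self.W.value.reshape(oc, ckk)
        dcols = (w2.T @ dT).reshape(self.in_c, k * k, n, ho, wo)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dx[:, :, ki:ki + ho, kj:kj + wo] += \
                    dcols[:, ki * k + kj].transpose(1, 0, 2, 3)
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma.value, self.beta.value,
                self.running_mean, self.running_var]

    def load_state(self, arrays):
        g, b, rm, rv = arrays
        self.gamma.value[...] = g
        self.beta.value[...] = b
        self.running_mean[...] = rm
        self.running_var[...] = rv

    def output_shape(self, in_shape):
        return in_shape

    def forward(self, x, training):
        # fused as y = a*x + b per channel to minimize passes over the
        # (large) conv activations; xhat is recomputed in backward
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        a = (self.gamma.value * inv).astype(x.dtype)
        b = (self.beta.value - mean * self.gamma.value * inv).astype(x.dtype)
        self._x, self._mean, self._inv, self._training = x, mean, inv, training
        out = x * a[None, :, None, None]
        out += b[None, :, None, None]
        return out

    def backward(self, dout):
        x, mean, inv = self._x, self._mean, self._inv
        sum_dy = dout.sum(axis=(0, 2, 3))
        sum_dy_x = np.einsum("nchw,nchw->c", dout, x, optimize=True)
        sum_dy_xhat = (sum_dy_x - mean * sum_dy) * inv
        self.gamma.grad[...] = sum_dy_xhat
        self.beta.grad[...] = sum_dy
        g = self.gamma.value
        if not self._training:
            c2 = (g * inv).astype(dout.dtype)
            return dout * c2[None, :, None, None]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        # dx = c2*dout + c1*x + c3 per channel (the usual batchnorm
        # gradient rearranged into an affine form)
        c2 = g * inv
        c1 = -g * inv * inv * sum_dy_xhat / n
        c3 = -c2 * sum_dy / n - c1 * mean
        dx = dout * c2.astype(dout.dtype)[None, :, None, None]
        dx += x * c1.astype(dout.dtype)[None, :, None, None]
        dx += c3.astype(dout.dtype)[None, :, None, None]
        return dx


class ReLU(Layer):
    def output_shape(self, in_shape):
        return in_shape

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """Max pooling with stride equal to the kernel size.

    Trailing rows/columns that do not fill a window are dropped, matching
    the usual floor convention for the output size.
    """

    def __init__(self, kernel_size: int):
        self.k = kernel_size

    def output_shape(self, in_shape):
        c, h, w = in_shape
        return (c, (h - self.k) // self.k + 1, (w - self.k) // self.k + 1)

    def forward(self, x, training):
        n, c, h, w = x.shape
        k = self.k
        ho, wo = (h - k) // k + 1, (w - k) // k + 1
        xv = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        # two-step max keeps every pass cheap; argmaxes stored for backward
        m1 = xv.max(axis=5)                      # (n, c, ho, k, wo)
        self._arg5 = xv.argmax(axis=5)
        self._arg3 = m1.argmax(axis=3)           # (n, c, ho, wo)
        self._x_shape = x.shape
        return np.take_along_axis(
            m1, self._arg3[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, c, h, w = self._x_shape
        k = self.k
        ho, wo = dout.shape[2], dout.shape[3]
        k3 = self._arg3
        k5 = np.take_along_axis(self._arg5, k3[:, :, :, None, :],
                                axis=3)[:, :, :, 0, :]
        # windows do not overlap: one flat assignment per output cell
        ni, ci, hi, wi = np.ix_(np.arange(n), np.arange(c),
                                np.arange(ho), np.arange(wo))
        flat = np.zeros(n * c * ho * k * wo * k, dtype=dout.dtype)
        idx = ((((ni * c + ci) * ho + hi) * k + k3) * wo + wi) * k + k5
        flat[idx.ravel()] = dout.ravel()
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, :, :ho * k, :wo * k] = flat.reshape(n, c, ho * k, wo * k)
        return dx


class GlobalMaxPool(Layer):
    """Adaptive max pooling to 1x1 followed by flatten: (N,C,H,W) -> (N,C)."""

    def output_shape(self, in_shape):
        return (in_shape[0],)

    def forward(self, x, training):
        out = x.max(axis=(2, 3))
        self._x, self._out = x, out
        return out

    def backward(self, dout):
        mask = (self._x == self._out[:, :, None, None])
        counts = mask.sum(axis=(2, 3), keepdims=True)
        return mask * (dout[:, :, None, None] / counts)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features),
                       size=(in_features, out_features))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(out_features, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def output_shape(self, in_shape):
        if in_shape != (self.W.value.shape[0],):
            raise ValueError(
                f"Dense expects input {self.W.value.shape[0]}, got {in_shape}")
        return (self.W.value.shape[1],)

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad[...] = self._x.T @ dout
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]

    def load_state(self, arrays):
        i = 0
        for layer in self.layers:
            k = len(layer.state_arrays())
            layer.load_state(arrays[i:i + k])
            i += k

    def output_shape(self, in_shape):
        shape = in_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
        return shape

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          sample_weights: np.ndarray | None = None):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are integer class indices; optional per-sample weights
    rescale both loss and gradient.
    """
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    logp = np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))
    if sample_weights is None:
        loss = -logp.mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
    else:
        wsum = sample_weights.sum()
        loss = -(sample_weights * logp).sum() / wsum
        dlogits = probs * sample_weights[:, None]
        dlogits[np.arange(n), labels] -= sample_weights
        dlogits /= wsum
    return loss, dlogits.astype(np.float32), probs


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
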