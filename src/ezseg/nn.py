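"""Compact CPU neural-network engine used by :mod:`ezseg.networks`.

Implements exactly the layer set the two segmentation networks need —
2-D convolution with "same" zero padding, batch normalization, ReLU,
2x2 max pooling, 2x2 stride-2 transposed convolution, fully connected
layers and a softmax cross-entropy head — together with stochastic
gradient descent with momentum.

Design notes
------------
Activations use NHWC ``float32`` layout.  Convolutions run as im2col
(a jitted gather) followed by one large BLAS matrix product per batch
slice, with a jitted scatter-add for the input gradient; the unfolded
buffers are shared across layers to avoid allocation churn.  All
randomness (weight init, shuffling) flows through an explicit
:class:`numpy.random.Generator`, so identical seeds give bit-identical
models.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


@njit(fastmath=True, cache=False)
def _im2col(xp3, k, ci, cols):  # pragma: no cover - exercised via Conv2d
    """Unfold padded input into (n*h*w, k*k*c_in) patch rows.

    ``xp3`` is the padded NHWC tensor viewed as (n, hp, wp*ci); for each
    kernel row the source pixels (k columns x c_in channels) are
    memory-contiguous, so the inner loop is a straight block copy.
    """
    n, hp, wpci = xp3.shape
    wp = wpci // ci
    h = hp - (k - 1)
    w = wp - (k - 1)
    kci = k * ci
    row = 0
    for nn in range(n):
        for r in range(h):
            for c in range(w):
                for i in range(k):
                    base = i * kci
                    off = c * ci
                    for t in range(kci):
                        cols[row, base + t] = xp3[nn, r + i, off + t]
                row += 1


@njit(fastmath=True, cache=False)
def _col2im_add(dcols, k, ci, dxp3):  # pragma: no cover - exercised via Conv2d
    """Scatter-add patch-row gradients back onto the padded input grid
    (viewed as (n, hp, wp*c_in))."""
    n, hp, wpci = dxp3.shape
    wp = wpci // ci
    h = hp - (k - 1)
    w = wp - (k - 1)
    kci = k * ci
    row = 0
    for nn in range(n):
        for r in range(h):
            for c in range(w):
                for i in range(k):
                    base = i * kci
                    off = c * ci
                    for t in range(kci):
                        dxp3[nn, r + i, off + t] += dcols[row, base + t]
                row += 1


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base class: layers expose forward/backward and their parameters."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2-D convolution (zero padding), NHWC."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.W = Param(glorot_uniform(rng, (kernel * kernel, c_in, c_out), fan_in, fan_out))
        self.b = Param(np.zeros(c_out, dtype=F32))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    # im2col via a jitted gather, one large BLAS GEMM per batch slice
    # (inner dimension k*k*c_in), and a jitted scatter-add for the input
    # gradient.  Slices keep the unfolded buffer a few hundred MB; the
    # padded input is cached and the buffer rebuilt during backward.

    _COL_BUDGET = 6 * 10**7  # max elements of one unfolded slice
    # shared scratch buffers (unfolded patches / their gradients), grown
    # on demand and reused across all layers to avoid allocation churn
    _scratch: dict[str, np.ndarray] = {}

    @classmethod
    def _buf(cls, name: str, n_elem: int) -> np.ndarray:
        buf = cls._scratch.get(name)
        if buf is None or buf.size < n_elem:
            buf = cls._scratch[name] = np.empty(n_elem, dtype=F32)
        return buf[:n_elem]

    def _chunk(self, n: int, h: int, w: int) -> int:
        per = h * w * self.k * self.k * self.c_in
        return max(1, min(n, int(self._COL_BUDGET // max(per, 1))))

    def _wmat(self) -> np.ndarray:
        return self.W.value.reshape(self.k * self.k * self.c_in, self.c_out)

    def forward(self, x, train):
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(np.asarray(x, dtype=F32), ((0, 0), (p, p), (p, p), (0, 0)))
        wmat = self._wmat()
        out = np.empty((n, h, w, self.c_out), dtype=F32)
        step = self._chunk(n, h, w)
        kk_ci = k * k * self.c_in
        for s in range(0, n, step):
            e = min(s + step, n)
            cb = self._buf("cols", (e - s) * h * w * kk_ci).reshape(-1, kk_ci)
            _im2col(xp[s:e].reshape(e - s, xp.shape[1], -1), k, self.c_in, cb)
            dst = out[s:e].reshape(-1, self.c_out)
            np.matmul(cb, wmat, out=dst)
            dst += self.b.value
        self._xp = xp if train else None
        return out

    def backward(self, dy):
        xp = self._xp
        n, h, w = dy.shape[:3]
        k, p = self.k, self.k // 2
        wmat = self._wmat()
        dxp = np.zeros_like(xp)
        step = self._chunk(n, h, w)
        kk_ci = k * k * self.c_in
        wmat_t = np.ascontiguousarray(wmat.T)
        for s in range(0, n, step):
            e = min(s + step, n)
            rows = (e - s) * h * w
            cb = self._buf("cols", rows * kk_ci).reshape(-1, kk_ci)
            _im2col(xp[s:e].reshape(e - s, xp.shape[1], -1), k, self.c_in, cb)
            dy2 = np.ascontiguousarray(dy[s:e]).reshape(-1, self.c_out)
            self.W.grad += (dy2.T @ cb).T.reshape(self.W.grad.shape)
            dcols = self._buf("dcols", rows * kk_ci).reshape(-1, kk_ci)
            np.matmul(dy2, wmat_t, out=dcols)
            _col2im_add(dcols, k, self.c_in, dxp[s:e].reshape(e - s, xp.shape[1], -1))
        self.b.grad += dy.reshape(-1, self.c_out).sum(axis=0)
        self._xp = None
        return dxp[:, p:p + h, p:p + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=F32))
        self.beta = Param(np.zeros(c, dtype=F32))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    # population-statistics accumulation: between begin_stats() and
    # end_stats(), inference passes normalise by batch statistics and
    # accumulate them, after which run_mean/run_var hold population
    # estimates over everything seen (rather than a lagging EMA)
    _accum: list | None = None

    def begin_stats(self):
        self._accum = [0, 0.0, 0.0]

    def end_stats(self):
        n, s1, s2 = self._accum
        if n:
            mean = s1 / n
            self.run_mean = mean.astype(F32)
            self.run_var = np.maximum(s2 / n - mean * mean, 0).astype(F32)
        self._accum = None

    def forward(self, x, train):
        axes = self._axes(x)
        if not train and self._accum is not None:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            a = self._accum
            a[0] += 1
            a[1] = a[1] + mean.astype(np.float64)
            a[2] = a[2] + (var + mean * mean).astype(np.float64)
            inv = 1.0 / np.sqrt(var + self.eps)
            return (((x - mean) * inv) * self.gamma.value + self.beta.value).astype(F32)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(F32))
        return (xhat * self.gamma.value + self.beta.value).astype(F32)

    def backward(self, dy):
        xhat, inv = self._cache
        axes = self._axes(dy)
        m = dy.size // dy.shape[-1]
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = dy * self.gamma.value
        dx = inv * (g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes))
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        flat = xc.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._inshape = idx, x.shape
        return np.ascontiguousarray(out)

    def backward(self, dy):
        n, h, w, c = self._inshape
        h2, w2 = h // 2, w // 2
        flat = np.zeros((n, h2, w2, c, 4), dtype=F32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        dxc = flat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c), dtype=F32)
        dx[:, : 2 * h2, : 2 * w2, :] = dxc.reshape(n, 2 * h2, 2 * w2, c)
        self._idx = None
        return dx


class ConvTranspose2x2(Layer):
    """2x2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(glorot_uniform(rng, (4, c_in, c_out), c_in, 4 * c_out))
        self.b = Param(np.zeros(c_out, dtype=F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, h, w, _ = x.shape
        out = np.empty((n, 2 * h, 2 * w, self.c_out), dtype=F32)
        x2 = x.reshape(-1, self.c_in)
        for idx in range(4):
            i, j = divmod(idx, 2)
            out[:, i::2, j::2, :] = (x2 @ self.W.value[idx] + self.b.value).reshape(n, h, w, self.c_out)
        if train:
            self._x2, self._shape = x2, (n, h, w)
        return out

    def backward(self, dy):
        n, h, w = self._shape
        dx2 = np.zeros((n * h * w, self.c_in), dtype=F32)
        for idx in range(4):
            i, j = divmod(idx, 2)
            d = np.ascontiguousarray(dy[:, i::2, j::2, :]).reshape(-1, self.c_out)
            self.W.grad[idx] += self._x2.T @ d
            self.b.grad += d.sum(axis=0)
            dx2 += d @ self.W.value[idx].T
        out = dx2.reshape(n, h, w, self.c_in)
        self._x2 = None
        return out


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out, dtype=F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=-1, keepdims=True)).astype(F32)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """(Weighted) mean cross-entropy over all leading axes.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the
    mean loss with respect to ``logits``.  ``labels`` holds integer class
    ids with shape ``logits.shape[:-1]``.  ``class_weights`` (length
    n_classes) rescales each sample by its true class's weight; the loss
    is normalised by the total weight, so uniform weights reduce to the
    plain mean.
    """
    p = softmax(logits)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_l = labels.reshape(-1)
    n = flat_l.shape[0]
    picked = flat_p[np.arange(n), flat_l]
    logs = -np.log(np.maximum(picked, 1e-12))
    if class_weights is None:
        loss = float(logs.mean())
        d = flat_p.copy()
        d[np.arange(n), flat_l] -= 1.0
        d /= n
    else:
        w = np.asarray(class_weights, dtype=np.float64)[flat_l]
        wsum = w.sum()
        loss = float((w * logs).sum() / wsum)
        d = flat_p * (w / wsum).astype(F32)[:, None]
        d[np.arange(n), flat_l] -= (w / wsum).astype(F32)
    return loss, d.reshape(logits.shape)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params, self.lr, self.momentum = params, lr, momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p in self.params:
            p.vel[...] = self.momentum * p.vel - self.lr * p.grad
            p.value += p.vel


def count_params(layer: Layer) -> int:
    return int(sum(p.value.size for p in layer.params()))
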