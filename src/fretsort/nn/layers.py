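"""Differentiable layers operating on (batch, time, channels) arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless unless it owns parameters.

    ``params`` / ``grads`` return parallel lists of arrays so optimizers can
    update in place.
    """

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(kernel: int) -> tuple[int, int]:
    # 'same' padding for stride 1; for even kernels the extra cell goes right
    left = (kernel - 1) // 2
    return left, kernel - 1 - left


class Conv1D(Layer):
    """1-D convolution (cross-correlation), stride 1, 'same' padding.

    Weights are He/variance-scaling initialized, the standard choice for
    ReLU-activated convolutions.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        std = np.sqrt(2.0 / (kernel * in_ch))
        self.w = rng.normal(0.0, std, size=(kernel, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        # the convolution is a sum of K shifted matmuls, which keeps the
        # work in BLAS without materializing an im2col buffer
        left, right = _same_pad(self.kernel)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._xp = xp
        t = x.shape[1]
        y = xp[:, 0:t, :] @ self.w[0]
        for k in range(1, self.kernel):
            y += xp[:, k : k + t, :] @ self.w[k]
        return y + self.b

    def backward(self, dy):
        xp = self._xp
        t = dy.shape[1]
        b, f = dy.shape[0], dy.shape[2]
        dyf = dy.reshape(b * t, f)
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            xk = np.ascontiguousarray(xp[:, k : k + t, :])
            self.dw[k] = xk.reshape(b * t, -1).T @ dyf
            dxp[:, k : k + t, :] += dy @ self.w[k].T
        self.db[:] = dy.sum(axis=(0, 1))
        left, right = _same_pad(self.kernel)
        return dxp[:, left : left + t, :]


class BatchNorm1D(Layer):
    """Batch normalization per channel over the (batch, time) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv_std, n = self._cache
        self.dgamma[:] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[:] = dy.sum(axis=(0, 1))
        # standard batchnorm gradient, reduced over batch and time
        dxhat = dy * self.gamma
        return (
            inv_std
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Max pooling with stride 1 and 'same' output length.

    Keeps the per-frame output contract (no temporal downsampling) while
    still providing local translation invariance.
    """

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training=False):
        self._shape = x.shape
        if self.pool == 2:  # fast path: pairwise maximum with its neighbor
            t = x.shape[1]
            xp = np.pad(x, ((0, 0), (0, 1), (0, 0)), constant_values=-np.inf)
            right_nb = xp[:, 1 : t + 1, :]
            sel = right_nb > x
            self._argmax = sel
            return np.where(sel, right_nb, x)
        left, right = _same_pad(self.pool)
        xp = np.pad(
            x, ((0, 0), (left, right), (0, 0)), constant_values=-np.inf
        )
        win = sliding_window_view(xp, self.pool, axis=1)  # (B, T, C, P)
        self._argmax = win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, dy):
        b, t, c = self._shape
        left, right = _same_pad(self.pool)
        dxp = np.zeros((b, t + left + right, c), dtype=dy.dtype)
        for p in range(self.pool):
            dxp[:, p : p + t, :] += dy * (self._argmax == p)
        return dxp[:, left : left + t, :]


class Dense(Layer):
    """Time-distributed affine map (applied independently per frame)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_dim + out_dim))  # Glorot-uniform
        self.w = rng.uniform(-limit, limit, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        x = self._x
        self.dw[:] = np.einsum("bti,btj->ij", x, dy, optimize=True)
        self.db[:] = dy.sum(axis=(0, 1))
        return dy @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy between softmax(logits) and target distributions.

    Targets may be soft (label-smoothed) rows.  Returns (loss, dlogits) with
    the gradient already averaged over batch x time.
    """
    p = softmax(logits)
    n = logits.shape[0] * logits.shape[1]
    loss = float(-(targets * np.log(p + 1e-12)).sum() / n)
    dlogits = (p - targets) / n
    return loss, dlogits
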