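"""Bidirectional LSTM with hand-written backpropagation through time.

Both directions are evaluated in a single time loop on arrays stacked
along a leading direction axis (shape ``(2, batch, ...)``), with the
per-direction weights stacked likewise so each step is one broadcast
matmul instead of two -- on small hidden sizes the Python-level call count,
not the arithmetic, is what costs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .layers import Layer


class BiLSTM(Layer):
    """Bidirectional LSTM returning the concatenated hidden sequences
    (output width ``2 * units``).

    Gate order in the fused weight matrices is (input, forget, output,
    cell) so the three sigmoid gates occupy one contiguous slab; the
    forget-gate bias starts at 1, the usual trick to let long-range
    information survive early training.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        limit = np.sqrt(6.0 / (in_dim + 4 * units))
        self.wx = rng.uniform(-limit, limit, size=(2, in_dim, 4 * units))
        # orthogonal recurrent init: QR of a Gaussian block per gate
        wh = np.empty((2, units, 4 * units))
        for d in range(2):
            for g in range(4):
                q, _ = np.linalg.qr(rng.normal(size=(units, units)))
                wh[d, :, g * units : (g + 1) * units] = q
        self.wh = wh
        self.b = np.zeros((2, 1, 1, 4 * units))
        self.b[..., units : 2 * units] = 1.0
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.wx, self.wh, self.b]

    def grads(self):
        return [self.dwx, self.dwh, self.db]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        # direction 0 reads forward, direction 1 reads time-reversed
        xs = np.stack([x, x[:, ::-1, :]])  # (2, B, T, C)
        h = np.zeros((2, b, u), dtype=x.dtype)
        c = np.zeros((2, b, u), dtype=x.dtype)
        hs = np.empty((2, b, t, u), dtype=x.dtype)
        cache = []
        x_proj = xs @ self.wx[:, None] + self.b  # (2, B, T, 4H)
        for step in range(t):
            z = x_proj[:, :, step, :] + h @ self.wh
            sig = expit(z[:, :, : 3 * u])
            i = sig[:, :, :u]
            f = sig[:, :, u : 2 * u]
            o = sig[:, :, 2 * u :]
            g = np.tanh(z[:, :, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, :, step, :] = h
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._cache = cache
        self._xs = xs
        return np.concatenate([hs[0], hs[1][:, ::-1, :]], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xs = self._xs
        _, b, t, _ = xs.shape
        u = self.units
        dh_seq = np.stack([dy[:, :, :u], dy[:, ::-1, u:]])  # (2, B, T, H)
        dh_next = np.zeros((2, b, u), dtype=xs.dtype)
        dc_next = np.zeros((2, b, u), dtype=xs.dtype)
        dz_all = np.empty((2, b, t, 4 * u), dtype=xs.dtype)
        self.dwh[:] = 0.0
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[step]
            dh = dh_seq[:, :, step, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dc_next = dc * f
            dz = dz_all[:, :, step, :]
            dz[:, :, :u] = dc * g * i * (1.0 - i)
            dz[:, :, u : 2 * u] = dc * c_prev * f * (1.0 - f)
            dz[:, :, 2 * u : 3 * u] = do * o * (1.0 - o)
            dz[:, :, 3 * u :] = dc * i * (1.0 - g * g)
            self.dwh += h_prev.transpose(0, 2, 1) @ dz
            dh_next = dz @ self.wh.transpose(0, 2, 1)
        dz_flat = dz_all.reshape(2, b * t, 4 * u)
        xs_flat = xs.reshape(2, b * t, -1)
        self.dwx[:] = xs_flat.transpose(0, 2, 1) @ dz_flat
        self.db[:] = dz_all.sum(axis=(1, 2), keepdims=True)
        dxs = (dz_flat @ self.wx.transpose(0, 2, 1)).reshape(xs.shape)
        return dxs[0] + dxs[1][:, ::-1, :]
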