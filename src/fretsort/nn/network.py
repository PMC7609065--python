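"""Residual convolutional + bidirectional-LSTM per-frame sequence classifier.

Architecture (per-frame labeling, so every stage preserves trace length):

* initial convolution (same hyperparameters as the first residual block),
  batch norm, ReLU;
* a stack of residual blocks.  Block ``j`` (0-based) uses
  ``base_filters * 2**(j // doubling_period)`` filters and a kernel of
  ``kernel_start - kernel_decrement * (j // doubling_period)`` (never below
  ``kernel_min``), so early blocks see large-scale features and deep blocks
  progressively smaller ones.  Each block is
  Conv(k) -> BN -> ReLU -> Conv(1x1) -> BN, added to a shortcut copy of its
  input (1x1-projected when the filter count changes), ReLU, then stride-1
  max pooling;
* a bidirectional LSTM with dropout on its outputs;
* a time-distributed dense layer to the six class logits.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    MaxPool1D,
    ReLU,
    softmax,
)
from .recurrent import BiLSTM


class ResidualBlock:
    def __init__(
        self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator
    ):
        self.conv1 = Conv1D(in_ch, out_ch, kernel, rng)
        self.bn1 = BatchNorm1D(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(out_ch, out_ch, 1, rng)  # 1x1 bottleneck conv
        self.bn2 = BatchNorm1D(out_ch)
        self.project = None
        self.bn_proj = None
        if in_ch != out_ch:
            self.project = Conv1D(in_ch, out_ch, 1, rng)
            self.bn_proj = BatchNorm1D(out_ch)
        self.relu_out = ReLU()
        self.pool = MaxPool1D(2)

    def _layers(self):
        layers = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.project is not None:
            layers += [self.project, self.bn_proj]
        return layers

    def params(self):
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self):
        return [g for layer in self._layers() for g in layer.grads()]

    def forward(self, x, training=False):
        y = self.conv1.forward(x, training)
        y = self.bn1.forward(y, training)
        y = self.relu1.forward(y, training)
        y = self.conv2.forward(y, training)
        y = self.bn2.forward(y, training)
        if self.project is not None:
            shortcut = self.bn_proj.forward(self.project.forward(x, training), training)
        else:
            shortcut = x
        y = self.relu_out.forward(y + shortcut, training)
        return self.pool.forward(y, training)

    def backward(self, dy):
        dy = self.pool.backward(dy)
        dy = self.relu_out.backward(dy)
        dshort = dy
        d = self.bn2.backward(dy)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.conv1.backward(d)
        if self.project is not None:
            dx = dx + self.project.backward(self.bn_proj.backward(dshort))
        else:
            dx = dx + dshort
        return dx


class SequenceClassifier:
    """(B, T, n_channels) -> (B, T, n_classes) per-frame classifier."""

    def __init__(
        self,
        n_channels: int,
        n_classes: int = 6,
        n_res_blocks: int = 16,
        base_filters: int = 32,
        filter_doubling_period: int = 4,
        kernel_start: int = 16,
        kernel_decrement: int = 4,
        kernel_min: int = 4,
        recurrent_units: int = 16,
        recurrent_dropout_rate: float = 0.4,
        seed: int = 0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        filters, kernels = self.schedule(
            n_res_blocks,
            base_filters,
            filter_doubling_period,
            kernel_start,
            kernel_decrement,
            kernel_min,
        )
        self.filters, self.kernels = filters, kernels
        self.conv_in = Conv1D(n_channels, filters[0], kernels[0], rng)
        self.bn_in = BatchNorm1D(filters[0])
        self.relu_in = ReLU()
        self.blocks: list[ResidualBlock] = []
        in_ch = filters[0]
        for f, k in zip(filters, kernels):
            self.blocks.append(ResidualBlock(in_ch, f, k, rng))
            in_ch = f
        self.lstm = BiLSTM(in_ch, recurrent_units, rng)
        self.dropout = Dropout(recurrent_dropout_rate, rng)
        self.head = Dense(2 * recurrent_units, n_classes, rng)
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.dtype = np.dtype(dtype)
        self._cast_parameters()

    def _cast_parameters(self) -> None:
        # single-precision arithmetic is plenty for SGD and halves the
        # training cost; float64 remains available for gradient checking
        def cast(obj, depth=0):
            if depth > 3:
                return
            for attr, val in list(vars(obj).items()):
                if isinstance(val, np.ndarray) and val.dtype == np.float64:
                    setattr(obj, attr, val.astype(self.dtype))
                elif hasattr(val, "__dict__") and not isinstance(val, np.dtype):
                    cast(val, depth + 1)

        for m in [self.conv_in, self.bn_in] + self.blocks + [self.lstm, self.head]:
            cast(m)

    @staticmethod
    def schedule(
        n_blocks: int,
        base_filters: int,
        doubling_period: int,
        kernel_start: int,
        kernel_decrement: int,
        kernel_min: int = 4,
    ) -> tuple[list[int], list[int]]:
        """Per-block (filters, kernel) schedule from the stated rules."""
        filters, kernels = [], []
        for j in range(n_blocks):
            stage = j // doubling_period
            filters.append(base_filters * 2**stage)
            kernels.append(max(kernel_start - kernel_decrement * stage, kernel_min))
        return filters, kernels

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        return (
            [self.conv_in, self.bn_in]
            + self.blocks
            + [self.lstm, self.head]
        )

    def params(self) -> list[np.ndarray]:
        return [p for m in self._modules() for p in m.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for m in self._modules() for g in m.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        weights = [p.copy() for p in self.params()]
        for m in self._iter_batchnorms():
            weights.append(m.running_mean.copy())
            weights.append(m.running_var.copy())
        return weights

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        for p, w in zip(params, weights[: len(params)]):
            p[:] = w
        rest = weights[len(params) :]
        for i, m in enumerate(self._iter_batchnorms()):
            m.running_mean[:] = rest[2 * i]
            m.running_var[:] = rest[2 * i + 1]

    def _iter_batchnorms(self):
        yield self.bn_in
        for blk in self.blocks:
            yield blk.bn1
            yield blk.bn2
            if blk.bn_proj is not None:
                yield blk.bn_proj

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (B, T, n_classes)."""
        if x.ndim != 3 or x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected input with {self.n_channels} channels, got shape {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=self.dtype)
        y = self.relu_in.forward(
            self.bn_in.forward(self.conv_in.forward(x, training), training), training
        )
        for blk in self.blocks:
            y = blk.forward(y, training)
        y = self.lstm.forward(y, training)
        y = self.dropout.forward(y, training)
        return self.head.forward(y, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.lstm.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        d = self.relu_in.backward(d)
        d = self.bn_in.backward(d)
        self.conv_in.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Row-stochastic per-frame class probabilities (evaluation mode)."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(outs, axis=0) if outs else np.empty((0, 0, self.n_classes))
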