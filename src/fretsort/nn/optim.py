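"""Adam optimizer and training-schedule helpers."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive-moment estimation with bias correction (default lr 0.001)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Divide the learning rate by ``factor`` after ``patience`` consecutive
    epochs without validation-loss improvement."""

    def __init__(self, optimizer: Adam, factor: float = 10.0, patience: int = 2):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def step(self, val_loss: float) -> bool:
        """Returns True if the learning rate was reduced this epoch."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            self.optimizer.lr /= self.factor
            self.wait = 0
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement,
    remembering the best parameter snapshot."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.wait = 0
        self.best_weights: list[np.ndarray] | None = None

    def step(self, val_loss: float, params: list[np.ndarray]) -> bool:
        """Returns True when training should stop."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.wait = 0
            self.best_weights = [p.copy() for p in params]
            return False
        self.wait += 1
        return self.wait >= self.patience

    def restore(self, params: list[np.ndarray]) -> None:
        if self.best_weights is not None:
            for p, b in zip(params, self.best_weights):
                p[:] = b
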