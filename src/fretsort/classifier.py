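"""Training and application of the per-frame six-class trace classifier.

The classifier maps a normalized intensity trace (T frames x 2 or 3
channels) to a T x 6 row-stochastic matrix of per-frame class probabilities
over (B, A, N, X, S, D).  Training minimizes cross-entropy against
label-smoothed targets with Adam in batches of 32, reducing the learning
rate tenfold after two epochs without validation improvement and stopping
early after five.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .nn.layers import softmax, softmax_cross_entropy
from .nn.network import SequenceClassifier
from .nn.optim import Adam, EarlyStopping, ReduceLROnPlateau
from .trace import CLASSES, Trace


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    Defaults are the full-scale network: 16 residual blocks whose filter
    count starts at 32 (2^5) and doubles every 4th block while the kernel
    size shrinks from 16 by 4 every 4th block down to 4, a 16-unit
    bidirectional LSTM with 0.4 output dropout, and a softmax head.
    """

    n_channels: int = 3
    n_classes: int = 6
    n_res_blocks: int = 16
    base_filters: int = 32
    filter_doubling_period: int = 4
    kernel_start: int = 16
    kernel_decrement: int = 4
    kernel_min: int = 4
    recurrent_units: int = 16
    recurrent_dropout_rate: float = 0.4

    def __post_init__(self) -> None:
        if self.n_channels not in (2, 3):
            raise ValueError("n_channels must be 2 (non-ALEX) or 3 (ALEX)")

    def schedule(self) -> tuple[list[int], list[int]]:
        return SequenceClassifier.schedule(
            self.n_res_blocks,
            self.base_filters,
            self.filter_doubling_period,
            self.kernel_start,
            self.kernel_decrement,
            self.kernel_min,
        )


@dataclass
class TrainingConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay_factor: float = 10.0
    lr_patience: int = 2
    early_stop_patience: int = 5
    max_epochs: int = 100
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def normalize_trace(trace: Trace) -> Trace:
    """Divide all channels by the single global maximum over all channels.

    Preserves the relative intensities between donor and acceptor and makes
    predictions independent of instrument units.  Raises ``ValueError`` when
    the trace has no strictly positive value to normalize by.
    """
    stack = trace.channel_stack()
    m = stack.max()
    if not m > 0:
        raise ValueError("cannot normalize an all-nonpositive trace")
    out = trace.copy()
    out.dd /= m
    out.da /= m
    if out.aa is not None:
        out.aa /= m
    return out


def build_model(spec: ModelSpec, seed: int = 0) -> SequenceClassifier:
    """Instantiate the untrained network for a spec (deterministic in seed)."""
    return SequenceClassifier(
        n_channels=spec.n_channels,
        n_classes=spec.n_classes,
        n_res_blocks=spec.n_res_blocks,
        base_filters=spec.base_filters,
        filter_doubling_period=spec.filter_doubling_period,
        kernel_start=spec.kernel_start,
        kernel_decrement=spec.kernel_decrement,
        kernel_min=spec.kernel_min,
        recurrent_units=spec.recurrent_units,
        recurrent_dropout_rate=spec.recurrent_dropout_rate,
        seed=seed,
    )


@dataclass
class TrainedModel:
    """A trained network bundled with its spec and the fixed class order."""

    network: SequenceClassifier
    spec: ModelSpec
    classes: tuple[str, ...] = CLASSES
    history: dict = field(default_factory=dict)

    def save(self, path) -> None:
        meta = {
            "spec": asdict(self.spec),
            "classes": list(self.classes),
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
        }
        weights = self.network.get_weights()
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            **{f"w{i}": w for i, w in enumerate(weights)},
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        spec = ModelSpec(**meta["spec"])
        net = build_model(spec, seed=0)
        expected = len(net.get_weights())
        if expected != len(weights):
            raise ValueError("weight file does not match the architecture spec")
        net.set_weights(weights)
        model = cls(network=net, spec=spec, classes=tuple(meta["classes"]))
        model.history = meta.get("history", {})
        return model


def _epoch_loss(net: SequenceClassifier, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        loss, _ = softmax_cross_entropy(net.forward(xb, training=False), yb)
        total += loss * len(xb)
        n += len(xb)
    return total / max(n, 1)


def train_model(
    x: np.ndarray,
    y: np.ndarray,
    spec: Optional[ModelSpec] = None,
    config: Optional[TrainingConfig] = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train the classifier on stacked (N, T, C) inputs and (N, T, 6) targets.

    Targets are label-smoothed distributions; inputs must already be
    normalized per trace.  The data is shuffled once and split into
    train/validation by ``train_fraction``.  Fully deterministic on CPU for a
    fixed seed.
    """
    if len(x) == 0:
        raise ValueError("cannot train on an empty dataset")
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    spec = spec or ModelSpec(n_channels=x.shape[2])
    config = config or TrainingConfig()
    if x.shape[2] != spec.n_channels:
        raise ValueError(
            f"data has {x.shape[2]} channels but spec expects {spec.n_channels}"
        )
    hard = y.argmax(axis=2)
    if len(np.unique(hard)) < 2:
        import warnings

        warnings.warn("training on a single-class dataset is degenerate")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_train = max(1, int(round(config.train_fraction * len(x))))
    if n_train == len(x):
        n_train = len(x) - 1
    tr, va = order[:n_train], order[n_train:]
    x_tr, y_tr = x[tr], y[tr]
    x_va, y_va = x[va], y[va]

    net = build_model(spec, seed=config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    plateau = ReduceLROnPlateau(opt, factor=config.lr_decay_factor,
                                patience=config.lr_patience)
    stopper = EarlyStopping(patience=config.early_stop_patience)
    history: dict[str, list[float]] = {"loss": [], "val_loss": [], "lr": []}

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        running, seen = 0.0, 0
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = net.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step(net.grads())
            running += loss * len(idx)
            seen += len(idx)
        train_loss = running / seen
        val_loss = _epoch_loss(net, x_va, y_va, config.batch_size)
        history["loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if verbose:
            print(
                f"epoch {epoch + 1}: loss={train_loss:.4f} "
                f"val_loss={val_loss:.4f} lr={opt.lr:.2e}"
            )
        stop = stopper.step(val_loss, net.params())
        plateau.step(val_loss)
        if stop:
            break
    stopper.restore(net.params())
    return TrainedModel(network=net, spec=spec, history=history)


def predict_frame_probs(model: TrainedModel, trace: Trace) -> np.ndarray:
    """T x 6 row-stochastic per-frame class probabilities for one trace.

    The trace is normalized to its global maximum first, so raw-unit traces
    can be passed directly.  Prediction is per-trace: no other trace in a
    batch can influence the output (batch norm runs in evaluation mode).
    """
    spec = model.spec
    if trace.n_channels != spec.n_channels:
        raise ValueError(
            f"trace has {trace.n_channels} channels but the model expects "
            f"{spec.n_channels} (ALEX vs non-ALEX mismatch)"
        )
    x = normalize_trace(trace).channel_stack()[None, :, :]
    return softmax(model.network.forward(x, training=False))[0]


def predict_batch(
    model: TrainedModel, traces: Sequence[Trace], batch_size: int = 64
) -> np.ndarray:
    """Stacked predictions for equally long traces: (N, T, 6)."""
    xs = []
    for tr in traces:
        if tr.n_channels != model.spec.n_channels:
            raise ValueError("trace/model channel mismatch")
        xs.append(normalize_trace(tr).channel_stack())
    x = np.asarray(xs)
    return model.network.predict_proba(x, batch_size=batch_size)
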