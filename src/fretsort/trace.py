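"""Core containers for smFRET time traces and their per-frame labels.

A trace is the universal unit of data: three background-corrected intensity
channels recorded under alternating laser excitation (ALEX) --

* ``dd`` -- donor excitation, donor emission
* ``da`` -- donor excitation, acceptor emission (the FRET channel)
* ``aa`` -- acceptor excitation, acceptor emission (absent for non-ALEX data)

from which the observable FRET efficiency ``E = DA / (DD + DA)`` and, for
ALEX data, the stoichiometry ``S = (DD + DA) / (DD + DA + AA)`` are derived.
Intensities are in arbitrary (detector) units; the simulator uses units of a
single fluorophore's emission, so a lone molecule peaks near 1 and an
aggregate of ``m`` molecules near ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Fixed per-frame class order used everywhere (arrays, model output, files):
#: bleached, aggregate, noisy, scrambled, static smFRET, dynamic smFRET.
CLASSES: tuple[str, ...] = ("B", "A", "N", "X", "S", "D")
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES = len(CLASSES)

#: Classes that count as usable smFRET when decisions are collapsed to binary.
SMFRET_CLASSES = frozenset({"S", "D"})


@dataclass
class Trace:
    """Intensity time trace; ``aa`` is ``None`` for non-ALEX recordings."""

    dd: np.ndarray
    da: np.ndarray
    aa: Optional[np.ndarray] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.dd = np.asarray(self.dd, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        if self.aa is not None:
            self.aa = np.asarray(self.aa, dtype=float)
        n = len(self.dd)
        if len(self.da) != n or (self.aa is not None and len(self.aa) != n):
            raise ValueError("all channels must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.dd)

    @property
    def is_alex(self) -> bool:
        return self.aa is not None

    @property
    def n_channels(self) -> int:
        return 3 if self.is_alex else 2

    def channel_stack(self) -> np.ndarray:
        """(n_frames, n_channels) array in DD, DA[, AA] order."""
        chans = [self.dd, self.da] + ([self.aa] if self.is_alex else [])
        return np.stack(chans, axis=1)

    def copy(self) -> "Trace":
        return Trace(
            self.dd.copy(),
            self.da.copy(),
            None if self.aa is None else self.aa.copy(),
            self.source_id,
        )


def observed_es(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame observable FRET efficiency and stoichiometry.

    ``E = DA / (DD + DA)`` and ``S = (DD + DA) / (DD + DA + AA)``.  Frames
    whose denominator is <= 0 yield NaN (undefined marker), never an
    exception.  For non-ALEX traces S is NaN everywhere.
    """
    dd, da = trace.dd, trace.da
    total = dd + da
    e = np.full(trace.n_frames, np.nan)
    ok = total > 0
    e[ok] = da[ok] / total[ok]
    s = np.full(trace.n_frames, np.nan)
    if trace.is_alex:
        denom = total + trace.aa
        ok = denom > 0
        s[ok] = total[ok] / denom[ok]
    return e, s


@dataclass
class FrameLabels:
    """Per-frame ground-truth class plus the label-smoothed distribution."""

    hard: np.ndarray  # (T,) int indices into CLASSES
    smoothed: np.ndarray  # (T, 6) rows sum to 1

    @classmethod
    def from_hard(cls, hard: np.ndarray, smoothing: float = 0.05) -> "FrameLabels":
        """Smoothed rows are ``(1 - eps) * onehot + eps / n_classes``."""
        hard = np.asarray(hard, dtype=int)
        onehot = np.eye(N_CLASSES)[hard]
        smoothed = (1.0 - smoothing) * onehot + smoothing / N_CLASSES
        return cls(hard=hard, smoothed=smoothed)

    def hard_symbols(self) -> list[str]:
        return [CLASSES[i] for i in self.hard]


@dataclass
class LabeledTrace:
    """A simulated trace bundled with ground truth."""

    trace: Trace
    labels: FrameLabels
    config: "TraceConfig"  # noqa: F821 - forward ref to simulate module
    ground_truth_fret: np.ndarray

    @property
    def first_frame_class(self) -> str:
        return CLASSES[self.labels.hard[0]]


@dataclass
class Dataset:
    """A collection of labeled traces, optionally tagged train/val/test."""

    traces: list[LabeledTrace] = field(default_factory=list)
    split_tag: str = ""

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    def first_frame_classes(self) -> list[str]:
        return [t.first_frame_class for t in self.traces]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for t in self.traces:
            counts[t.first_frame_class] += 1
        return counts


def stack_dataset(
    dataset: Sequence[LabeledTrace], alex: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into (N, T, C) inputs and (N, T, 6) smoothed targets.

    Each trace is normalized to its global channel maximum (model convention);
    traces that cannot be normalized (all-nonpositive) get zeros.
    """
    from .classifier import normalize_trace  # local import to avoid cycle

    xs, ys = [], []
    for lt in dataset:
        tr = lt.trace
        try:
            tr = normalize_trace(tr)
        except ValueError:
            tr = tr.copy()
        x = tr.channel_stack()
        if not alex and x.shape[1] == 3:
            x = x[:, :2]
        xs.append(x)
        ys.append(lt.labels.smoothed)
    return np.asarray(xs), np.asarray(ys)
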