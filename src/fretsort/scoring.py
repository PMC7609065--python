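"""From per-frame probabilities to a trace-level confidence and decision.

The per-frame bleached probability drives a sliding-window bleach cut; the
remaining live frames are averaged into five per-trace category scores, and
the static + dynamic smFRET scores sum to the trace's smFRET confidence
score -- the single quantity a user thresholds to accept traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trace import CLASS_INDEX

#: Category order of the five non-bleached per-trace scores.
SCORE_CLASSES = ("A", "N", "X", "S", "D")


def sliding_window_hits(
    hits: np.ndarray, window: int = 7, min_hits: int = 4
) -> Optional[int]:
    """First index ``i`` whose window ``[i, i + window - 1]`` (truncated at
    the end of the series) contains at least ``min_hits`` True values.

    Truncated end windows still require the full ``min_hits`` (conservative:
    avoids spurious calls at the very end of a trace).
    """
    hits = np.asarray(hits, dtype=bool)
    n = len(hits)
    if n == 0:
        return None
    csum = np.concatenate([[0], np.cumsum(hits)])
    starts = np.arange(n)
    ends = np.minimum(starts + window, n)
    counts = csum[ends] - csum[starts]
    idx = np.flatnonzero(counts >= min_hits)
    return int(idx[0]) if len(idx) else None


def detect_bleaching(
    p_bleached: np.ndarray,
    window: int = 7,
    min_hits: int = 4,
    p_thresh: float = 0.5,
) -> Optional[int]:
    """Bleach start frame from the per-frame bleached probability.

    A frame counts as a hit when ``p_B > p_thresh``; the first window with
    ``min_hits`` of ``window`` hits marks the bleach start, and every frame
    from that index onwards is considered bleached.  Returns ``None`` when no
    window qualifies.  The windowed vote prevents a single confidently
    'bleached' frame from truncating the trace.
    """
    return sliding_window_hits(
        np.asarray(p_bleached) > p_thresh, window=window, min_hits=min_hits
    )


@dataclass
class CategoryScores:
    """Per-trace averaged class scores and the smFRET confidence score.

    ``confidence = P_S + P_D``; the five scores are renormalized over the
    non-bleached categories so they sum to 1.  ``forced_bleached`` marks
    traces whose usable window was too short to score.
    """

    P_A: float
    P_N: float
    P_X: float
    P_S: float
    P_D: float
    confidence: float
    bleach_frame: Optional[int]
    n_live_frames: int
    forced_bleached: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.P_A, self.P_N, self.P_X, self.P_S, self.P_D])

    @property
    def assigned_class(self) -> str:
        if self.forced_bleached:
            return "B"
        return SCORE_CLASSES[int(np.argmax(self.as_array()))]


def score_trace(
    probs: np.ndarray,
    bleach_frame: Optional[int] = None,
    min_live: int = 15,
) -> CategoryScores:
    """Average the per-frame probabilities into per-trace category scores.

    Frames at/after ``bleach_frame`` are excluded.  ``P_i`` is the summed
    probability of category ``i`` over live frames divided by the total
    summed probability of the five non-bleached categories, so the five
    scores sum to exactly 1.  If bleaching strikes before ``min_live`` frames
    (or fewer than ``min_live`` live frames remain), the trace is classified
    bleached outright with confidence 0 -- scoring a handful of frames would
    artificially inflate the confidence.
    """
    probs = np.asarray(probs, dtype=float)
    n = len(probs)
    live_end = n if bleach_frame is None else int(np.clip(bleach_frame, 0, n))
    if live_end < min_live:
        return CategoryScores(
            P_A=0.0, P_N=0.0, P_X=0.0, P_S=0.0, P_D=0.0,
            confidence=0.0, bleach_frame=bleach_frame,
            n_live_frames=live_end, forced_bleached=True,
        )
    live = probs[:live_end]
    sums = live.sum(axis=0)
    five = np.array([sums[CLASS_INDEX[c]] for c in SCORE_CLASSES])
    total = five.sum()
    if total <= 0:
        five = np.zeros(5)
    else:
        five = five / total
    p = dict(zip(SCORE_CLASSES, five))
    return CategoryScores(
        P_A=float(p["A"]), P_N=float(p["N"]), P_X=float(p["X"]),
        P_S=float(p["S"]), P_D=float(p["D"]),
        confidence=float(p["S"] + p["D"]),
        bleach_frame=bleach_frame, n_live_frames=live_end,
    )


def score_from_probs(probs: np.ndarray, min_live: int = 15) -> CategoryScores:
    """Convenience: bleach detection + scoring in one call."""
    bleach = detect_bleaching(probs[:, CLASS_INDEX["B"]])
    return score_trace(probs, bleach_frame=bleach, min_live=min_live)


def classify_trace(
    scores: CategoryScores, threshold: float = 0.85
) -> tuple[bool, str]:
    """Accept/reject decision plus the assigned class.

    A trace is accepted iff its confidence score is >= the threshold
    (inclusive) and it was not force-classified as bleached.  Both static
    and dynamic smFRET count as acceptable; the assigned class is the argmax
    of the five category scores.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    accepted = (not scores.forced_bleached) and scores.confidence >= threshold
    return accepted, scores.assigned_class
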