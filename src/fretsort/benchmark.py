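"""Baseline threshold sorting and evaluation metrics.

Implements the 'simple thresholding' baseline a practitioner would apply by
hand -- median stoichiometry window, max-intensity bounds, presence of
bleaching -- plus precision/recall, confusion matrices and the scripted
mixed-population sorting experiment (a small known population of two-state
smFRET traces hidden in a large pool of artifact traces).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scoring import sliding_window_hits
from .simulate import SimulationParams, TraceConfig, simulate_trace
from .trace import CLASSES, LabeledTrace, SMFRET_CLASSES, Trace, observed_es


@dataclass
class SortThresholds:
    """Baseline acceptance thresholds.

    ``max_intensity_bounds`` are in normalized (single-fluorophore) units and
    bound the maximum live-frame intensity over all channels; the
    stoichiometry range bounds the median live-frame S.
    """

    stoichiometry_range: tuple[float, float] = (0.3, 0.7)
    max_intensity_bounds: tuple[float, float] = (0.0, np.inf)
    require_bleaching: bool = True

    def __post_init__(self) -> None:
        for name in ("stoichiometry_range", "max_intensity_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} not ordered")


@dataclass
class ConfusionCounts:
    Tp: int = 0
    Fp: int = 0
    Fn: int = 0
    Tn: int = 0

    @property
    def total(self) -> int:
        return self.Tp + self.Fp + self.Fn + self.Tn


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """P = Tp / (Tp + Fp), R = Tp / (Fn + Tp); NaN when undefined."""
    p = counts.Tp / (counts.Tp + counts.Fp) if (counts.Tp + counts.Fp) else np.nan
    r = counts.Tp / (counts.Fn + counts.Tp) if (counts.Fn + counts.Tp) else np.nan
    return p, r


def stoichiometry_bleach_index(
    s_obs: np.ndarray,
    window: int = 7,
    min_hits: int = 4,
    s_range: tuple[float, float] = (0.3, 0.7),
) -> Optional[int]:
    """Sliding-window bleach detection from the stoichiometry series.

    Same 4-of-7 window semantics as the probability-based detector, but a
    frame counts as a hit when its stoichiometry falls outside ``s_range``
    (undefined S counts as outside: no signal, no stoichiometry).
    """
    s = np.asarray(s_obs, dtype=float)
    if np.all(np.isnan(s)):
        raise ValueError("stoichiometry undefined everywhere (non-ALEX trace?)")
    lo, hi = s_range
    hits = ~((s > lo) & (s < hi))  # NaN comparisons are False -> hit
    return sliding_window_hits(hits, window=window, min_hits=min_hits)


def _sort_one(trace: Trace, thresholds: SortThresholds) -> bool:
    e, s = observed_es(trace)
    bleach = stoichiometry_bleach_index(s, s_range=thresholds.stoichiometry_range)
    live_end = trace.n_frames if bleach is None else bleach
    if thresholds.require_bleaching and bleach is None:
        return False
    if live_end < 1:
        return False
    s_live = s[:live_end]
    s_live = s_live[~np.isnan(s_live)]
    if len(s_live) == 0:
        return False
    med = float(np.median(s_live))
    lo, hi = thresholds.stoichiometry_range
    if not (lo < med < hi):
        return False
    # single-molecule intensity: total donor-excited emission DD + DA
    max_int = float((trace.dd + trace.da)[:live_end].max())
    blo, bhi = thresholds.max_intensity_bounds
    return blo <= max_int <= bhi


def threshold_sort(
    traces: Sequence[LabeledTrace] | Sequence[Trace],
    thresholds: SortThresholds,
    truth: Optional[Sequence[bool]] = None,
) -> tuple[list[int], ConfusionCounts]:
    """Baseline sorter: indices of accepted traces + confusion counts.

    ``truth`` gives the ground-truth smFRET flag per trace; when omitted it
    is taken from the labels of :class:`LabeledTrace` inputs.
    """
    plain: list[Trace] = []
    flags: list[bool] = []
    for i, t in enumerate(traces):
        if isinstance(t, LabeledTrace):
            plain.append(t.trace)
            flags.append(t.first_frame_class in SMFRET_CLASSES)
        else:
            plain.append(t)
            flags.append(bool(truth[i]) if truth is not None else False)
    if truth is not None:
        flags = [bool(v) for v in truth]
    counts = ConfusionCounts()
    accepted: list[int] = []
    for i, (tr, is_pos) in enumerate(zip(plain, flags)):
        ok = _sort_one(tr, thresholds)
        if ok:
            accepted.append(i)
        if ok and is_pos:
            counts.Tp += 1
        elif ok and not is_pos:
            counts.Fp += 1
        elif not ok and is_pos:
            counts.Fn += 1
        else:
            counts.Tn += 1
    return accepted, counts


# ---------------------------------------------------------------------------
# confusion matrices


def confusion_matrix(
    predicted: Sequence[str], truth: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """6x6 counts (rows: predicted class, columns: ground truth) plus the
    row-normalized fractions.  Works at frame or trace level -- the caller
    decides what one item is."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth label sets differ in length")
    k = len(CLASSES)
    idx = {c: i for i, c in enumerate(CLASSES)}
    counts = np.zeros((k, k), dtype=int)
    for p, t in zip(predicted.ravel(), truth.ravel()):
        counts[idx[str(p)], idx[str(t)]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(row_sums > 0, counts / row_sums, 0.0)
    return counts, frac


def collapse_binary(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Collapse 6-class labels to binary smFRET (S or D) vs non-smFRET."""
    counts = ConfusionCounts()
    for p, t in zip(predicted, truth):
        pp = p in SMFRET_CLASSES
        tt = t in SMFRET_CLASSES
        if pp and tt:
            counts.Tp += 1
        elif pp and not tt:
            counts.Fp += 1
        elif not pp and tt:
            counts.Fn += 1
        else:
            counts.Tn += 1
    return counts


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """(TPR + TNR) / 2 from binary confusion counts."""
    tpr = counts.Tp / (counts.Tp + counts.Fn) if (counts.Tp + counts.Fn) else np.nan
    tnr = counts.Tn / (counts.Tn + counts.Fp) if (counts.Tn + counts.Fp) else np.nan
    return (tpr + tnr) / 2.0


def precision_recall_curve(
    scores: Sequence[float],
    truth: Sequence[bool],
    thresholds: Sequence[float],
) -> list[dict]:
    """Precision/recall of score-threshold acceptance over a threshold grid."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    rows = []
    for thr in thresholds:
        acc = scores >= thr
        counts = ConfusionCounts(
            Tp=int(np.sum(acc & truth)),
            Fp=int(np.sum(acc & ~truth)),
            Fn=int(np.sum(~acc & truth)),
            Tn=int(np.sum(~acc & ~truth)),
        )
        p, r = precision_recall(counts)
        rows.append(
            {"threshold": float(thr), "precision": p, "recall": r,
             "n_accepted": int(acc.sum())}
        )
    return rows


# ---------------------------------------------------------------------------
# the mixed-population sorting experiment


def performance_test_params(
    bleedthrough: float = 0.05, **overrides
) -> SimulationParams:
    """Priors for the benchmark population: training priors except a fixed
    noise sigma of 0.11 and a fixed 5% donor bleedthrough."""
    defaults = dict(
        noise_sigma_range=(0.11, 0.11),
        bleedthrough_range=(bleedthrough, bleedthrough),
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


def simulate_ground_truth_smfret(
    n: int,
    fret_states: Sequence[float] = (0.3, 0.7),
    trans_prob: float = 0.1,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
    require_bleaching: bool = True,
) -> list[LabeledTrace]:
    """Known-good smFRET traces at fixed states/kinetics.

    Ground-truth traces that never photobleach within the observation window
    are discarded (their usable window cannot be delimited) and resampled.
    """
    params = params or performance_test_params()
    rng = np.random.default_rng(seed)
    fret_states = np.asarray(fret_states, dtype=float)
    out: list[LabeledTrace] = []
    while len(out) < n:
        blink_events = []
        if rng.uniform() < params.p_blink:
            for _ in range(rng.poisson(params.blink_mean_events)):
                blink_events.append(
                    (
                        int(rng.integers(0, params.n_frames)),
                        1 + int(rng.exponential(params.blink_mean_duration)),
                        "donor" if rng.uniform() < 0.5 else "acceptor",
                    )
                )
        falloff = (
            int(rng.exponential(params.falloff_lifetime))
            if rng.uniform() < params.p_falloff
            else None
        )
        cfg = TraceConfig(
            trace_class="smFRET",
            n_states=len(fret_states),
            fret_values=fret_states.copy(),
            trans_prob=trans_prob if len(fret_states) > 1 else 0.0,
            noise_sigma=rng.uniform(*params.noise_sigma_range),
            has_gamma_noise=bool(rng.uniform() < params.p_gamma_noise),
            aa_mismatch=rng.uniform(*params.aa_mismatch_range),
            bleedthrough=rng.uniform(*params.bleedthrough_range),
            donor_bleach_frame=int(rng.exponential(params.bleach_lifetime)),
            acceptor_bleach_frame=int(rng.exponential(params.bleach_lifetime)),
            falloff_frame=falloff,
            blink_events=blink_events,
            aggregate_size=None,
            scramble_mode=None,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        dark = max(cfg.donor_bleach_frame, cfg.acceptor_bleach_frame)
        if cfg.falloff_frame is not None:
            dark = min(dark, cfg.falloff_frame)
        if require_bleaching and dark >= params.n_frames:
            continue
        if dark < 1:
            continue
        out.append(simulate_trace(params, rng, config=cfg))
    return out


def simulate_non_smfret(
    n: int,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
) -> list[LabeledTrace]:
    """Artifact traces (aggregate / noisy / scrambled first-frame class).

    Drawn at the full training priors -- in particular the whole noise-sigma
    range, so genuinely 'too noisy' traces are represented -- since this pool
    emulates the random junk a raw experiment produces.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    out: list[LabeledTrace] = []
    while len(out) < n:
        lt = simulate_trace(params, rng)
        if lt.first_frame_class in ("A", "N", "X"):
            out.append(lt)
    return out


#: Coarse tight-to-loose grid of max-intensity bounds (single-fluorophore
#: units) swept by the baseline sorter.
DEFAULT_INTENSITY_GRID: tuple[tuple[float, float], ...] = tuple(
    (lo, hi) for lo in (0.3, 0.6, 0.9) for hi in (1.3, 1.6, 2.0)
)


def run_sorting_experiment(
    seed: int = 0,
    n_smfret: int = 200,
    n_other: int = 5000,
    fret_states: Sequence[float] = (0.3, 0.7),
    trans_prob: float = 0.1,
    intensity_grid: Sequence[tuple[float, float]] = DEFAULT_INTENSITY_GRID,
    model=None,
    score_thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.85),
) -> dict:
    """Mixed-population sorting benchmark.

    Simulates ``n_smfret`` ground-truth smFRET traces mixed with ``n_other``
    artifact traces, runs the baseline threshold sorter over a grid of
    max-intensity bounds, and (when a trained model is supplied) the
    confidence-score classifier over ``score_thresholds``.  Reports per-grid
    precision/recall, the best-precision grid point, and FRET histogram data.
    """
    params = performance_test_params()
    good = simulate_ground_truth_smfret(
        n_smfret, fret_states=fret_states, trans_prob=trans_prob,
        params=params, seed=seed,
    )
    bad = simulate_non_smfret(n_other, seed=seed + 1)
    population = good + bad
    truth = [True] * len(good) + [False] * len(bad)

    grid_rows = []
    for lo, hi in intensity_grid:
        thr = SortThresholds(max_intensity_bounds=(lo, hi))
        accepted, counts = threshold_sort(population, thr, truth=truth)
        p, r = precision_recall(counts)
        grid_rows.append(
            {
                "intensity_lo": lo, "intensity_hi": hi,
                "Tp": counts.Tp, "Fp": counts.Fp, "Fn": counts.Fn,
                "Tn": counts.Tn, "precision": p, "recall": r,
                "n_accepted": len(accepted),
            }
        )
    defined = [row for row in grid_rows if not np.isnan(row["precision"])]
    best = max(defined, key=lambda row: row["precision"]) if defined else None

    # ground-truth FRET histogram data (live frames of the true population)
    gt_fret: list[np.ndarray] = []
    for lt in good:
        e, _ = observed_es(lt.trace)
        live = ~np.isnan(lt.ground_truth_fret)
        gt_fret.append(e[live])
    report = {
        "seed": seed,
        "n_smfret": len(good),
        "n_other": len(bad),
        "grid": grid_rows,
        "best": best,
        "ground_truth_fret": np.concatenate(gt_fret) if gt_fret else np.empty(0),
    }

    if model is not None:
        from .classifier import predict_batch
        from .scoring import score_from_probs

        probs = predict_batch(model, [lt.trace for lt in population])
        scores = [score_from_probs(p).confidence for p in probs]
        report["model_curve"] = precision_recall_curve(
            scores, truth, score_thresholds
        )
        report["model_scores"] = np.asarray(scores)
    return report
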