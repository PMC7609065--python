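"""Kinetic analysis of accepted traces.

Gaussian-emission hidden Markov models are fit per trace by Baum-Welch
(expectation-maximization), the number of FRET states is chosen by the
Bayesian information criterion, and the idealized state paths are reduced to
dwell-time and transition-density statistics -- the quantities a kineticist
reads off a dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .trace import Trace, observed_es

logging.getLogger("hmmlearn").setLevel(logging.ERROR)


@dataclass
class IdealizedTrace:
    """HMM idealization of one trace.

    States are sorted by ascending FRET mean; ``bic = -2 logL + k ln(n)``
    with ``k = K(K-1)`` free transition parameters + K means + K variances
    + (K-1) start probabilities.
    """

    state_path: np.ndarray
    state_means: np.ndarray
    transition_matrix: np.ndarray
    log_likelihood: float
    bic: float
    n_states: int


def _quantile_init_means(obs: np.ndarray, k: int) -> np.ndarray:
    """Quantile-spaced initial means: deterministic and order-preserving."""
    qs = (np.arange(k) + 0.5) / k
    return np.quantile(obs, qs, axis=0)


def n_free_parameters(k: int) -> int:
    return k * (k - 1) + k + k + (k - 1)


def fit_hmm(
    trace: Trace | np.ndarray,
    n_states: int,
    observation: str = "fret",
    seed: int = 0,
    n_iter: int = 100,
    live_end: Optional[int] = None,
    e_range: tuple[float, float] = (-0.5, 1.5),
) -> IdealizedTrace:
    """Fit a Gaussian HMM to the live portion of a trace.

    ``observation='fret'`` fits the 1-D FRET efficiency series;
    ``observation='channels'`` fits the 2-D (DD, DA) series, the two-channel
    mode in which state FRET means are derived from the fitted channel
    means.  In FRET mode, frames whose apparent efficiency falls outside
    ``e_range`` are dropped before fitting: near-zero total intensity (a
    blink, or residual frames around a bleach) turns the DA/(DD+DA) ratio
    into an unbounded noise quotient that would otherwise spawn phantom
    states.  The state path is the most probable (Viterbi) path.  The fit
    is deterministic: means start at quantiles, the transition matrix at a
    diagonally dominant uniform.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if isinstance(trace, Trace):
        if observation == "fret":
            e, _ = observed_es(trace)
            # E is a ratio: frames where the total donor-excited intensity
            # collapses (blinks, bleach edges) carry no FRET information
            total = trace.dd + trace.da
            ref = np.nanmedian(total[: live_end if live_end else None])
            e = np.where(total > 0.25 * max(ref, 0.0), e, np.nan)
            obs = e[:, None]
        elif observation == "channels":
            obs = np.stack([trace.dd, trace.da], axis=1)
        else:
            raise ValueError("observation must be 'fret' or 'channels'")
    else:
        obs = np.asarray(trace, dtype=float)
        if obs.ndim == 1:
            obs = obs[:, None]
    if live_end is not None:
        obs = obs[:live_end]
    obs = obs[~np.isnan(obs).any(axis=1)]
    if obs.shape[1] == 1:
        obs = obs[(obs[:, 0] >= e_range[0]) & (obs[:, 0] <= e_range[1])]
    n = len(obs)
    if n < n_states + 2:
        raise ValueError(
            f"only {n} usable frames; cannot fit {n_states} states"
        )

    k = n_states
    hmm = GaussianHMM(
        n_components=k,
        covariance_type="diag",
        n_iter=n_iter,
        tol=1e-4,
        random_state=seed,
        init_params="",
        params="stmc",
        min_covar=1e-4,
    )
    hmm.startprob_ = np.full(k, 1.0 / k)
    if k == 1:
        hmm.transmat_ = np.ones((1, 1))
    else:
        off = 0.05 / (k - 1)
        hmm.transmat_ = np.full((k, k), off) + (0.95 - off) * np.eye(k)
    hmm.means_ = _quantile_init_means(obs, k)
    spread = max(obs.std(), 1e-3)
    hmm.covars_ = np.full((k, obs.shape[1]), (spread / max(k, 2)) ** 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm.fit(obs)
        log_l = float(hmm.score(obs))
        path = hmm.predict(obs)

    means = hmm.means_
    if isinstance(trace, Trace) and observation == "channels":
        dd_m, da_m = means[:, 0], means[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            fret_means = np.where(dd_m + da_m != 0, da_m / (dd_m + da_m), np.nan)
    else:
        fret_means = means[:, 0]
    order = np.argsort(fret_means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    bic = -2.0 * log_l + n_free_parameters(k) * np.log(n)
    return IdealizedTrace(
        state_path=relabel[path],
        state_means=np.asarray(fret_means)[order],
        transition_matrix=hmm.transmat_[np.ix_(order, order)],
        log_likelihood=log_l,
        bic=float(bic),
        n_states=k,
    )


def select_n_states_bic(
    trace: Trace | np.ndarray,
    k_max: int = 4,
    observation: str = "fret",
    seed: int = 0,
    live_end: Optional[int] = None,
) -> tuple[IdealizedTrace, list[dict]]:
    """Fit K = 1..k_max and return the BIC-minimizing idealization.

    Ties (within floating precision) break toward fewer states.  The second
    return value tabulates per-K BIC and log-likelihood.
    """
    table: list[dict] = []
    best: Optional[IdealizedTrace] = None
    for k in range(1, k_max + 1):
        try:
            ideal = fit_hmm(
                trace, k, observation=observation, seed=seed, live_end=live_end
            )
        except ValueError:
            break
        table.append(
            {"n_states": k, "bic": ideal.bic, "log_likelihood": ideal.log_likelihood}
        )
        if best is None or ideal.bic < best.bic - 1e-9:
            best = ideal
    if best is None:
        raise ValueError("no state count could be fitted")
    return best, table


def merge_degenerate_states(
    ideal: IdealizedTrace, min_separation: float = 0.05
) -> IdealizedTrace:
    """Merge states whose FRET means are closer than ``min_separation``.

    BIC occasionally splits one physical state into two nearly coincident
    Gaussians (skewed noise is the usual culprit).  States are merged
    greedily from the closest pair; the merged mean is the
    occupancy-weighted average and the transition matrix is re-estimated by
    counting transitions in the relabeled path.  Log-likelihood and BIC are
    kept from the original fit (they describe the unmerged model).
    """
    path = np.asarray(ideal.state_path).copy()
    means = np.asarray(ideal.state_means, dtype=float).copy()
    while len(means) > 1:
        gaps = np.diff(means)
        j = int(np.argmin(gaps))
        if gaps[j] >= min_separation:
            break
        w0 = np.sum(path == j)
        w1 = np.sum(path == j + 1)
        merged = (means[j] * w0 + means[j + 1] * w1) / max(w0 + w1, 1)
        means = np.delete(means, j + 1)
        means[j] = merged
        path[path == j + 1] = j
        path[path > j + 1] -= 1
    k = len(means)
    trans = np.zeros((k, k))
    np.add.at(trans, (path[:-1], path[1:]), 1)
    for i in range(k):
        total = trans[i].sum()
        if total > 0:
            trans[i] /= total
        else:
            trans[i, i] = 1.0
    return IdealizedTrace(
        state_path=path,
        state_means=means,
        transition_matrix=trans,
        log_likelihood=ideal.log_likelihood,
        bic=ideal.bic,
        n_states=k,
    )


# ---------------------------------------------------------------------------
# dwell statistics


@dataclass
class Dwell:
    state: int
    duration: int
    censored: bool  # last dwell of a trace: end never observed
    mean_fret: float


@dataclass
class DwellStats:
    dwells: list[Dwell] = field(default_factory=list)
    lifetimes: dict = field(default_factory=dict)  # state -> {mean, ci, n}
    tdp: Optional[np.ndarray] = None  # 2-D density over (FRET before, after)
    tdp_edges: Optional[np.ndarray] = None
    transitions: list[tuple[float, float]] = field(default_factory=list)


def segment_dwells(idealized: IdealizedTrace) -> list[Dwell]:
    """Split a state path into constant-state dwells; the final dwell is
    censored (its true end lies beyond the observation window)."""
    path = np.asarray(idealized.state_path)
    if len(path) == 0:
        return []
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(path)]])
    dwells = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        st = int(path[a])
        dwells.append(
            Dwell(
                state=st,
                duration=int(b - a),
                censored=(i == len(starts) - 1),
                mean_fret=float(idealized.state_means[st]),
            )
        )
    return dwells


def dwell_statistics(
    idealized: Sequence[IdealizedTrace],
    tdp_bins: int = 50,
    tdp_range: tuple[float, float] = (0.0, 1.0),
) -> DwellStats:
    """Aggregate dwell, lifetime and transition-density statistics.

    Censored final dwells are excluded from the exponential lifetime fits
    (MLE mean of uncensored dwells, with a normal-approximation 95% CI).
    The transition-density plot (TDP) is the 2-D histogram of (FRET before,
    FRET after) over all observed transitions.
    """
    if len(idealized) == 0:
        raise ValueError("need at least one idealized trace")
    stats = DwellStats()
    for ideal in idealized:
        dwells = segment_dwells(ideal)
        stats.dwells.extend(dwells)
        for before, after in zip(dwells[:-1], dwells[1:]):
            stats.transitions.append((before.mean_fret, after.mean_fret))

    by_state: dict[int, list[int]] = {}
    for d in stats.dwells:
        if not d.censored:
            by_state.setdefault(d.state, []).append(d.duration)
    for state, durations in sorted(by_state.items()):
        arr = np.asarray(durations, dtype=float)
        mean = float(arr.mean())  # MLE of the exponential mean
        se = mean / np.sqrt(len(arr))
        stats.lifetimes[state] = {
            "mean": mean,
            "ci95": (mean - 1.96 * se, mean + 1.96 * se),
            "n": len(arr),
        }
    if stats.transitions:
        before, after = np.array(stats.transitions).T
        hist, xe, _ = np.histogram2d(
            before, after, bins=tdp_bins, range=[tdp_range, tdp_range]
        )
        stats.tdp = hist
        stats.tdp_edges = xe
    else:
        stats.tdp = np.zeros((tdp_bins, tdp_bins))
        stats.tdp_edges = np.linspace(*tdp_range, tdp_bins + 1)
    return stats
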