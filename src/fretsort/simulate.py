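"""Generative simulator for ground-truth smFRET traces.

The simulator is the sole source of training and benchmark data.  Each trace
is drawn from a hierarchical generative model:

1. a latent :class:`TraceConfig` is sampled from population priors
   (:class:`SimulationParams`) -- trace class, FRET states, kinetics,
   photobleaching times, artifact parameters;
2. a hidden Markov state sequence produces per-frame ideal FRET values;
3. ideal unit intensities are derived (``DD = 1 - E``, ``DA = E``, ``AA = 1``);
4. photophysics (bleaching, blinking, fall-off, aggregation) is applied;
5. scrambling replaces the trace for artifact traces;
6. detection artifacts (acceptor mismatch, donor bleedthrough, Gaussian and
   centered-Gamma noise) are added;
7. every frame receives one of six ground-truth labels
   (bleached / aggregate / noisy / scrambled / static / dynamic).

All randomness flows through ``numpy.random.Generator``; a dataset is
reproduced bit-identically from its seed, with per-trace child seeds spawned
by counter so traces can be generated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .trace import (
    CLASSES,
    CLASS_INDEX,
    Dataset,
    FrameLabels,
    LabeledTrace,
    Trace,
)

#: Elementary scramble transformations; a scramble mode descriptor is one of
#: these, optionally prefixed with "miscolocalized+" when the source channels
#: come from two independent (wrongly colocalized) molecules.
SCRAMBLE_MODES = ("flip", "correlate", "bursts", "dark")


@dataclass
class SimulationParams:
    """Population priors for trace generation.

    Defaults are the training-set conditions: up to four FRET states uniform
    on [0, 1] separated by >= 0.1, per-frame per-destination transition
    probability uniform on [0, 0.2], exponential photobleaching with mean
    500 frames, 15% aggregates, 15% scrambles (90% of those mis-colocalized),
    20% blinking among non-aggregates, acceptor-only mismatch 70-130%, donor
    bleedthrough 0-15%, Gaussian noise sigma uniform on [0.01, 0.30] with an
    80%-probable centered Gamma(1, 1.1) component, 300-frame traces.
    """

    n_frames: int = 300
    max_states: int = 4
    min_state_separation: float = 0.1
    trans_prob_range: tuple[float, float] = (0.0, 0.2)
    p_aggregate: float = 0.15
    p_blink: float = 0.20
    p_scramble: float = 0.15
    p_scramble_colocalized: float = 0.90
    aa_mismatch_range: tuple[float, float] = (0.70, 1.30)
    bleedthrough_range: tuple[float, float] = (0.00, 0.15)
    noise_sigma_range: tuple[float, float] = (0.01, 0.30)
    p_gamma_noise: float = 0.8
    gamma_shape: float = 1.0
    gamma_scale: float = 1.1
    bleach_lifetime: float = 500.0
    p_falloff: float = 0.1
    falloff_lifetime: float = 500.0
    noisy_sigma_threshold: float = 0.25
    label_smoothing: float = 0.05
    aggregate_size_range: tuple[int, int] = (2, 10)
    blink_mean_events: float = 1.0
    blink_mean_duration: float = 5.0

    def __post_init__(self) -> None:
        probs = {
            "p_aggregate": self.p_aggregate,
            "p_blink": self.p_blink,
            "p_scramble": self.p_scramble,
            "p_scramble_colocalized": self.p_scramble_colocalized,
            "p_gamma_noise": self.p_gamma_noise,
            "p_falloff": self.p_falloff,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_aggregate + self.p_scramble > 1.0:
            raise ValueError("p_aggregate + p_scramble must not exceed 1")
        for name in (
            "trans_prob_range",
            "aa_mismatch_range",
            "bleedthrough_range",
            "noise_sigma_range",
            "aggregate_size_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} not ordered: {lo} > {hi}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bleach_lifetime <= 0:
            raise ValueError("bleach_lifetime must be positive")
        if (self.max_states - 1) * self.min_state_separation > 1.0 + 1e-9:
            raise ValueError(
                "impossible separation: cannot place "
                f"{self.max_states} states at least {self.min_state_separation} apart in [0, 1]"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in (
            "trans_prob_range",
            "aa_mismatch_range",
            "bleedthrough_range",
            "noise_sigma_range",
            "aggregate_size_range",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TraceConfig:
    """Latent generative choices for a single trace."""

    trace_class: str  # aggregate | scrambled | smFRET
    n_states: int
    fret_values: np.ndarray
    trans_prob: float
    noise_sigma: float
    has_gamma_noise: bool
    aa_mismatch: float
    bleedthrough: float
    donor_bleach_frame: int
    acceptor_bleach_frame: int
    falloff_frame: Optional[int]
    blink_events: list  # (start, duration, channel) with channel in {donor, acceptor}
    aggregate_size: Optional[int]
    scramble_mode: Optional[str]
    rng_seed: int

    def __post_init__(self) -> None:
        self.fret_values = np.asarray(self.fret_values, dtype=float)
        if len(self.fret_values) != self.n_states:
            raise ValueError("len(fret_values) must equal n_states")
        if self.trans_prob * (self.n_states - 1) > 1.0 + 1e-12:
            raise ValueError("total leave probability exceeds 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fret_values"] = [float(v) for v in self.fret_values]
        d["blink_events"] = [list(ev) for ev in self.blink_events]
        return d


# ---------------------------------------------------------------------------
# config sampling


def _sample_fret_values(
    n_states: int, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample n_states values uniform on [0,1], pairwise >= min_sep apart."""
    if (n_states - 1) * min_sep > 1.0 + 1e-9:
        raise ValueError("impossible separation")
    while True:
        vals = rng.uniform(0.0, 1.0, size=n_states)
        if n_states == 1:
            return vals
        s = np.sort(vals)
        if np.min(np.diff(s)) >= min_sep:
            return vals


def sample_trace_config(
    params: SimulationParams, rng: np.random.Generator
) -> TraceConfig:
    """Draw one latent trace configuration from the population priors."""
    u = rng.uniform()
    if u < params.p_aggregate:
        trace_class = "aggregate"
    elif u < params.p_aggregate + params.p_scramble:
        trace_class = "scrambled"
    else:
        trace_class = "smFRET"

    n_states = int(rng.integers(1, params.max_states + 1))
    fret_values = _sample_fret_values(n_states, params.min_state_separation, rng)
    trans_prob = rng.uniform(*params.trans_prob_range)
    # cap so the total leave probability never exceeds 1 for any state count
    if n_states > 1:
        trans_prob = min(trans_prob, 1.0 / (n_states - 1))
    noise_sigma = rng.uniform(*params.noise_sigma_range)
    has_gamma = bool(rng.uniform() < params.p_gamma_noise)
    aa_mismatch = rng.uniform(*params.aa_mismatch_range)
    bleedthrough = rng.uniform(*params.bleedthrough_range)

    donor_bleach = int(rng.exponential(params.bleach_lifetime))
    acceptor_bleach = int(rng.exponential(params.bleach_lifetime))
    falloff = None
    if rng.uniform() < params.p_falloff:
        falloff = int(rng.exponential(params.falloff_lifetime))

    blink_events: list[tuple[int, int, str]] = []
    if trace_class != "aggregate" and rng.uniform() < params.p_blink:
        n_events = rng.poisson(params.blink_mean_events)
        for _ in range(n_events):
            start = int(rng.integers(0, params.n_frames))
            duration = 1 + int(rng.exponential(params.blink_mean_duration))
            channel = "donor" if rng.uniform() < 0.5 else "acceptor"
            blink_events.append((start, duration, channel))

    aggregate_size = None
    if trace_class == "aggregate":
        lo, hi = params.aggregate_size_range
        aggregate_size = int(rng.integers(lo, hi + 1))

    scramble_mode = None
    if trace_class == "scrambled":
        # one aggressive transformation is always applied (scrambles are
        # deliberately non-physical); in most cases the source channels
        # additionally come from two incorrectly colocalized molecules
        scramble_mode = str(rng.choice(SCRAMBLE_MODES))
        if rng.uniform() < params.p_scramble_colocalized:
            scramble_mode = "miscolocalized+" + scramble_mode

    return TraceConfig(
        trace_class=trace_class,
        n_states=n_states,
        fret_values=fret_values,
        trans_prob=float(trans_prob),
        noise_sigma=float(noise_sigma),
        has_gamma_noise=has_gamma,
        aa_mismatch=float(aa_mismatch),
        bleedthrough=float(bleedthrough),
        donor_bleach_frame=donor_bleach,
        acceptor_bleach_frame=acceptor_bleach,
        falloff_frame=falloff,
        blink_events=blink_events,
        aggregate_size=aggregate_size,
        scramble_mode=scramble_mode,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# state sequence and ideal intensities


def sample_state_sequence(
    config: TraceConfig, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Markov state-index sequence: uniform start; per frame, jump to each of
    the other ``n_states - 1`` states with probability ``trans_prob``.

    Because the destination (given a jump) is uniform over the other states,
    the chain is simulated without a frame loop: the state is the start state
    plus the cumulative sum of random nonzero offsets at jump frames, mod n.
    """
    n = config.n_states
    if n == 1:
        return np.zeros(n_frames, dtype=int)
    p_leave = config.trans_prob * (n - 1)
    start = rng.integers(0, n)
    jumps = rng.uniform(size=n_frames - 1) < p_leave
    offsets = rng.integers(1, n, size=n_frames - 1)
    steps = np.where(jumps, offsets, 0)
    states = np.empty(n_frames, dtype=int)
    states[0] = start
    states[1:] = (start + np.cumsum(steps)) % n
    return states


def ideal_intensities(state_seq: np.ndarray, fret_values: np.ndarray) -> Trace:
    """Noiseless unit-intensity channels for a state sequence.

    With unit total emission, ``DD = 1 - E`` and the FRET channel follows from
    inverting ``E = DA / (DD + DA)``: ``DA = -(DD * E) / (E - 1)``, with the
    ``E == 1`` limit ``DA = 1``.  ``AA = 1`` regardless of the FRET state, so
    the ideal stoichiometry is exactly 0.5.
    """
    e = np.asarray(fret_values, dtype=float)[np.asarray(state_seq, dtype=int)]
    dd = 1.0 - e
    da = np.where(e >= 1.0, 1.0, -(dd * e) / np.where(e >= 1.0, 1.0, e - 1.0))
    aa = np.ones_like(dd)
    return Trace(dd=dd, da=da, aa=aa)


# ---------------------------------------------------------------------------
# photophysics


def _blink_mask(
    events: list, n_frames: int, channel: str
) -> np.ndarray:
    """Boolean mask of frames where the given fluorophore is blinked dark."""
    mask = np.zeros(n_frames, dtype=bool)
    for start, duration, chan in events:
        if chan == channel and start < n_frames:
            mask[start : min(start + duration, n_frames)] = True
    return mask


def _apply_pair_photophysics(
    ideal: Trace,
    donor_bleach: int,
    acceptor_bleach: int,
    blink_events: list,
) -> Trace:
    """Bleaching/blinking for one donor-acceptor pair.

    Donor dark (bleach or blink): DD = DA = 0 and AA persists (acceptor is
    still directly excited).  Acceptor dark: DA = AA = 0 and the donor
    recovers its full unit intensity (no more energy transfer).  Both dark:
    all channels 0.  Blinking is temporary; bleaching permanent.
    """
    t = np.arange(ideal.n_frames)
    donor_dark = (t >= donor_bleach) | _blink_mask(blink_events, ideal.n_frames, "donor")
    acceptor_dark = (t >= acceptor_bleach) | _blink_mask(
        blink_events, ideal.n_frames, "acceptor"
    )
    dd = ideal.dd.copy()
    da = ideal.da.copy()
    aa = ideal.aa.copy()
    dd[acceptor_dark & ~donor_dark] = 1.0  # full donor recovery
    da[acceptor_dark] = 0.0
    aa[acceptor_dark] = 0.0
    dd[donor_dark] = 0.0
    da[donor_dark] = 0.0
    return Trace(dd=dd, da=da, aa=aa)


def apply_photophysics(
    ideal: Trace, config: TraceConfig, params: SimulationParams, rng: np.random.Generator
) -> tuple[Trace, int]:
    """Apply bleaching, blinking, fall-off and (for aggregates) multi-pair
    summation.  Returns the trace and the first all-dark frame (may equal
    ``n_frames`` if the trace never fully bleaches within the observation).
    """
    n = ideal.n_frames
    if config.trace_class == "aggregate":
        size = config.aggregate_size or 2
        dd = np.zeros(n)
        da = np.zeros(n)
        aa = np.zeros(n)
        dark_frame = 0
        for _ in range(size):
            seq = sample_state_sequence(config, n, rng)
            pair_ideal = ideal_intensities(seq, config.fret_values)
            d_bleach = int(rng.exponential(params.bleach_lifetime))
            a_bleach = int(rng.exponential(params.bleach_lifetime))
            pair = _apply_pair_photophysics(pair_ideal, d_bleach, a_bleach, [])
            dd += pair.dd
            da += pair.da
            aa += pair.aa
            dark_frame = max(dark_frame, max(d_bleach, a_bleach))
        out = Trace(dd=dd, da=da, aa=aa)
    else:
        out = _apply_pair_photophysics(
            ideal,
            config.donor_bleach_frame,
            config.acceptor_bleach_frame,
            config.blink_events,
        )
        dark_frame = max(config.donor_bleach_frame, config.acceptor_bleach_frame)

    if config.falloff_frame is not None:
        f = config.falloff_frame
        if f < n:
            out.dd[f:] = 0.0
            out.da[f:] = 0.0
            out.aa[f:] = 0.0
        dark_frame = min(dark_frame, f)
    return out, min(dark_frame, n)


# ---------------------------------------------------------------------------
# scrambling


def _simulate_clean_pair(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[Trace, int]:
    """An independent plain smFRET molecule (used for mis-colocalization)."""
    n_states = int(rng.integers(1, params.max_states + 1))
    fret = _sample_fret_values(n_states, params.min_state_separation, rng)
    trans = rng.uniform(*params.trans_prob_range)
    if n_states > 1:
        trans = min(trans, 1.0 / (n_states - 1))
    cfg = TraceConfig(
        trace_class="smFRET",
        n_states=n_states,
        fret_values=fret,
        trans_prob=float(trans),
        noise_sigma=0.0,
        has_gamma_noise=False,
        aa_mismatch=1.0,
        bleedthrough=0.0,
        donor_bleach_frame=int(rng.exponential(params.bleach_lifetime)),
        acceptor_bleach_frame=int(rng.exponential(params.bleach_lifetime)),
        falloff_frame=None,
        blink_events=[],
        aggregate_size=None,
        scramble_mode=None,
        rng_seed=0,
    )
    seq = sample_state_sequence(cfg, params.n_frames, rng)
    ideal = ideal_intensities(seq, cfg.fret_values)
    return apply_photophysics(ideal, cfg, params, rng)


def apply_scramble(
    trace: Trace,
    config: TraceConfig,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[Trace, int]:
    """Replace/transform the trace according to the scramble mode descriptor.

    Scrambled traces are deliberately non-physical (they teach the
    classifier to reject aberrant data), so one aggressive elementary
    transformation is always applied:

    * ``flip`` -- one channel reversed in time;
    * ``correlate`` -- one channel replaced by the product of two channels,
      rescaled to unit maximum (strong positive correlation);
    * ``bursts`` -- random segments replaced by high-amplitude noise;
    * ``dark`` -- random long segments zeroed.

    When the descriptor carries the ``miscolocalized+`` prefix (most
    scrambles), the source channels first come from two independent
    molecules -- DD from one, DA/AA from the other -- emulating incorrect
    colocalization.  A bare ``miscolocalized`` descriptor applies only that
    replacement.  Returns the scrambled trace and its nominal all-dark frame.
    """
    parts = (config.scramble_mode or "").split("+")
    miscolocalized = "miscolocalized" in parts
    mode = next((p for p in parts if p != "miscolocalized"), None)
    n = trace.n_frames
    dark_frame = max(config.donor_bleach_frame, config.acceptor_bleach_frame)
    if config.falloff_frame is not None:
        dark_frame = min(dark_frame, config.falloff_frame)
    dark_frame = min(dark_frame, n)

    if miscolocalized:
        mol1, dark1 = _simulate_clean_pair(params, rng)
        mol2, dark2 = _simulate_clean_pair(params, rng)
        trace = Trace(dd=mol1.dd.copy(), da=mol2.da.copy(), aa=mol2.aa.copy())
        dark_frame = min(max(dark1, dark2), n)
    if mode is None:
        return trace if miscolocalized else trace.copy(), dark_frame

    out = trace.copy()
    channels = [out.dd, out.da, out.aa]
    if mode == "flip":
        idx = int(rng.integers(0, 3))
        channels[idx][:] = channels[idx][::-1].copy()
    elif mode == "correlate":
        i, j = rng.choice(3, size=2, replace=False)
        prod = channels[i] * channels[j]
        m = prod.max()
        if m > 0:
            prod = prod / m
        channels[int(i)][:] = prod
    elif mode == "bursts":
        n_bursts = 1 + int(rng.poisson(2))
        for _ in range(n_bursts):
            start = int(rng.integers(0, n))
            length = 1 + int(rng.exponential(20))
            stop = min(start + length, n)
            amp = rng.uniform(1.5, 4.0)
            for ch in channels:
                ch[start:stop] = np.abs(rng.normal(0.0, amp, size=stop - start))
        dark_frame = n  # bursts may re-light "bleached" frames
    elif mode == "dark":
        n_seg = 1 + int(rng.poisson(1))
        for _ in range(n_seg):
            start = int(rng.integers(0, n))
            length = 10 + int(rng.exponential(50))
            stop = min(start + length, n)
            for ch in channels:
                ch[start:stop] = 0.0
    else:  # pragma: no cover - guarded by sample_trace_config
        raise ValueError(f"unknown scramble mode: {mode}")
    return out, dark_frame


# ---------------------------------------------------------------------------
# detection artifacts


def add_detection_artifacts(
    trace: Trace, config: TraceConfig, params: SimulationParams, rng: np.random.Generator
) -> Trace:
    """Acceptor-only mismatch, donor bleedthrough and per-frame noise.

    ``AA`` is scaled by the mismatch fraction; a ``bleedthrough`` fraction of
    DD leaks into DA; then Gaussian noise ``Normal(0, sigma)`` (sigma in units
    of the maximum single-fluorophore intensity, i.e. 1) is added per frame
    and channel, with an optional skewed component drawn from a centered
    Gamma(k, theta) (the Gamma minus its mean ``k * theta``), also scaled by
    sigma.  Noise is added to bleached (zeroed) frames too, emulating
    detector readout.
    """
    out = trace.copy()
    out.aa *= config.aa_mismatch
    out.da += config.bleedthrough * out.dd
    sigma = config.noise_sigma
    shape = (trace.n_frames, 3)
    noise = rng.normal(0.0, sigma, size=shape)
    if config.has_gamma_noise:
        gamma_mean = params.gamma_shape * params.gamma_scale
        noise += (
            rng.gamma(params.gamma_shape, params.gamma_scale, size=shape) - gamma_mean
        ) * sigma
    out.dd += noise[:, 0]
    out.da += noise[:, 1]
    out.aa += noise[:, 2]
    return out


# ---------------------------------------------------------------------------
# labeling


def label_frames(
    config: TraceConfig,
    dark_frame: int,
    state_seq: np.ndarray,
    params: SimulationParams,
) -> FrameLabels:
    """Ground-truth per-frame labels.

    Frames at/after the all-dark (both-bleached or fall-off) frame are
    bleached (B).  Live frames carry the trace class: aggregate (A) and
    scrambled (X) take precedence, then noisy (N) if the drawn sigma exceeds
    the noisy threshold, else static (S) or dynamic (D) depending on whether
    any transition occurs within the observed pre-bleach window.
    """
    n = params.n_frames
    dark_frame = int(np.clip(dark_frame, 0, n))
    if config.trace_class == "aggregate":
        live_class = "A"
    elif config.trace_class == "scrambled":
        live_class = "X"
    elif config.noise_sigma > params.noisy_sigma_threshold:
        live_class = "N"
    else:
        observed = state_seq[:dark_frame]
        dynamic = len(observed) > 1 and np.any(np.diff(observed) != 0)
        live_class = "D" if dynamic else "S"
    hard = np.full(n, CLASS_INDEX["B"], dtype=int)
    hard[:dark_frame] = CLASS_INDEX[live_class]
    return FrameLabels.from_hard(hard, smoothing=params.label_smoothing)


# ---------------------------------------------------------------------------
# full pipeline


def simulate_trace(
    params: SimulationParams,
    rng: np.random.Generator,
    config: Optional[TraceConfig] = None,
) -> LabeledTrace:
    """Simulate one labeled trace end to end."""
    if config is None:
        config = sample_trace_config(params, rng)
    trace_rng = np.random.default_rng(config.rng_seed)
    state_seq = sample_state_sequence(config, params.n_frames, trace_rng)
    ideal = ideal_intensities(state_seq, config.fret_values)
    ground_truth_fret = config.fret_values[state_seq].copy()
    trace, dark_frame = apply_photophysics(ideal, config, params, trace_rng)
    if config.trace_class == "scrambled":
        trace, dark_frame = apply_scramble(trace, config, params, trace_rng)
    ground_truth_fret[dark_frame:] = np.nan
    trace = add_detection_artifacts(trace, config, params, trace_rng)
    labels = label_frames(config, dark_frame, state_seq, params)
    return LabeledTrace(
        trace=trace, labels=labels, config=config, ground_truth_fret=ground_truth_fret
    )


def first_frame_class(
    config: TraceConfig, params: SimulationParams
) -> str:
    """First-frame ground-truth class without synthesizing intensities.

    Reproduces exactly what :func:`simulate_trace` + :func:`label_frames`
    would assign to frame 0, at a fraction of the cost; used for streaming
    large balancing runs.
    """
    trace_rng = np.random.default_rng(config.rng_seed)
    state_seq = sample_state_sequence(config, params.n_frames, trace_rng)
    if config.trace_class == "aggregate":
        # replicate the aggregate pair loop's bleach draws
        size = config.aggregate_size or 2
        dark = 0
        for _ in range(size):
            sample_state_sequence(config, params.n_frames, trace_rng)
            d = int(trace_rng.exponential(params.bleach_lifetime))
            a = int(trace_rng.exponential(params.bleach_lifetime))
            dark = max(dark, max(d, a))
        if config.falloff_frame is not None:
            dark = min(dark, config.falloff_frame)
    elif config.trace_class == "scrambled":
        parts = (config.scramble_mode or "").split("+")
        if "miscolocalized" in parts:
            # fall-off does not apply: channels come from two other
            # molecules whose photophysics already fixed the dark frame
            darks = []
            for _ in range(2):
                _, dk = _simulate_clean_pair(params, trace_rng)
                darks.append(dk)
            dark = max(darks)
        else:
            dark = max(config.donor_bleach_frame, config.acceptor_bleach_frame)
            if config.falloff_frame is not None:
                dark = min(dark, config.falloff_frame)
        if "bursts" in parts:
            dark = params.n_frames  # bursts re-light "bleached" frames
    else:
        dark = max(config.donor_bleach_frame, config.acceptor_bleach_frame)
        if config.falloff_frame is not None:
            dark = min(dark, config.falloff_frame)
    dark = min(dark, params.n_frames)
    labels = label_frames(config, dark, state_seq, params)
    return CLASSES[labels.hard[0]]


def trace_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-trace seeds derived from a dataset seed by counter."""
    root = np.random.default_rng(seed)
    return root.integers(0, 2**31 - 1, size=n)


def generate_dataset(
    n_initial: int,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
    balance: bool = True,
) -> Dataset:
    """Simulate ``n_initial`` traces and under-sample to balance classes.

    Traces with no live frame (bleached from frame 0) are dropped, then the
    five non-bleached first-frame classes are under-sampled to the count of
    the rarest class.  Deterministic for fixed seed and params.
    """
    params = params or SimulationParams()
    seeds = trace_seeds(seed, n_initial) if n_initial else np.empty(0, dtype=int)
    traces: list[LabeledTrace] = []
    for s in seeds:
        traces.append(simulate_trace(params, np.random.default_rng(s)))
    if not balance:
        return Dataset(traces=traces)
    keep_idx = balanced_indices(
        [t.first_frame_class for t in traces], np.random.default_rng(seed + 1)
    )
    return Dataset(traces=[traces[i] for i in keep_idx])


def balanced_indices(
    first_classes: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Indices of an under-sampled, class-balanced subset.

    Bleached-from-start traces (class B) are dropped; each remaining class is
    randomly down-sampled (without replacement) to the rarest class's count.
    Returned indices are sorted so dataset order stays stable.
    """
    arr = np.asarray(first_classes)
    classes = [c for c in CLASSES if c != "B"]
    counts = {c: int(np.sum(arr == c)) for c in classes}
    present = {c: n for c, n in counts.items() if n > 0}
    if not present:
        return np.empty(0, dtype=int)
    n_keep = min(present.values())
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(arr == c)
        if len(idx) == 0:
            continue
        keep.append(rng.choice(idx, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


def balanced_count_stream(
    n_initial: int,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
) -> tuple[int, dict[str, int]]:
    """Size of the balanced dataset for ``n_initial`` traces, streaming.

    Computes first-frame classes one trace at a time (via the lean label
    path) so arbitrarily large balancing runs fit in memory.  Returns the
    retained-trace count and the raw per-class first-frame counts.
    """
    params = params or SimulationParams()
    seeds = trace_seeds(seed, n_initial)
    counts = {c: 0 for c in CLASSES}
    for s in seeds:
        rng = np.random.default_rng(s)
        cfg = sample_trace_config(params, rng)
        counts[first_frame_class(cfg, params)] += 1
    nonbleached = {c: n for c, n in counts.items() if c != "B" and n > 0}
    retained = 5 * min(nonbleached.values()) if len(nonbleached) == 5 else (
        len(nonbleached) * min(nonbleached.values()) if nonbleached else 0
    )
    return retained, counts
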