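"""Simulator: priors, kinetics, photophysics, artifacts and labeling."""

import numpy as np
import pytest

from fretsort import (
    CLASSES,
    SimulationParams,
    observed_es,
    sample_state_sequence,
    sample_trace_config,
    simulate_trace,
)
from fretsort.simulate import (
    add_detection_artifacts,
    apply_photophysics,
    apply_scramble,
    balanced_indices,
    first_frame_class,
    generate_dataset,
    ideal_intensities,
    label_frames,
)
from fretsort.trace import FrameLabels, Trace


# ---------------------------------------------------------------------------
# config sampling


def test_impossible_state_separation_rejected():
    with pytest.raises(ValueError, match="separation"):
        SimulationParams(max_states=4, min_state_separation=0.5)


def test_degenerate_aggregate_prior(rng):
    params = SimulationParams(p_aggregate=1.0, p_scramble=0.0)
    for _ in range(20):
        assert sample_trace_config(params, rng).trace_class == "aggregate"


def test_aggregate_fraction_matches_prior(rng):
    params = SimulationParams()
    n = 10_000
    k = sum(
        sample_trace_config(params, rng).trace_class == "aggregate"
        for _ in range(n)
    )
    se = np.sqrt(0.15 * 0.85 / n)
    assert abs(k / n - 0.15) < 3 * se


def test_fret_values_respect_min_separation(rng):
    params = SimulationParams()
    for _ in range(200):
        cfg = sample_trace_config(params, rng)
        assert np.all(cfg.fret_values >= 0) and np.all(cfg.fret_values <= 1)
        if cfg.n_states > 1:
            s = np.sort(cfg.fret_values)
            assert np.min(np.diff(s)) >= params.min_state_separation


def test_total_leave_probability_bounded(rng):
    # four states at per-destination probability p give total leave 3p <= 0.6
    params = SimulationParams()
    for _ in range(200):
        cfg = sample_trace_config(params, rng)
        assert cfg.trans_prob * (cfg.n_states - 1) <= 1.0 + 1e-12
        assert cfg.trans_prob <= 0.2


# ---------------------------------------------------------------------------
# state sequences


def test_state_sequence_constant_without_transitions(rng):
    cfg = _smfret_config(n_states=3, fret=[0.1, 0.5, 0.9], trans_prob=0.0)
    seq = sample_state_sequence(cfg, 500, rng)
    assert len(np.unique(seq)) == 1


def test_mean_dwell_matches_geometric(rng):
    # 2 states, leave prob 0.1 -> geometric dwells with mean 10 frames
    cfg = _smfret_config(n_states=2, fret=[0.3, 0.7], trans_prob=0.1)
    seq = sample_state_sequence(cfg, 200_000, rng)
    change = np.flatnonzero(np.diff(seq) != 0)
    dwells = np.diff(change)
    assert np.mean(dwells) == pytest.approx(10.0, rel=0.05)


def test_stay_frequency_four_states(rng):
    # per-destination 0.2 with 4 states -> stay probability 0.4
    cfg = _smfret_config(
        n_states=4, fret=[0.1, 0.35, 0.6, 0.85], trans_prob=0.2
    )
    seq = sample_state_sequence(cfg, 100_000, rng)
    stay = np.mean(np.diff(seq) == 0)
    assert stay == pytest.approx(0.4, abs=0.01)


def test_state_sequence_marginal_uniform(rng):
    # symmetric chain: occupancy uniform over states
    cfg = _smfret_config(n_states=4, fret=[0.1, 0.35, 0.6, 0.85], trans_prob=0.15)
    seq = sample_state_sequence(cfg, 200_000, rng)
    occ = np.bincount(seq, minlength=4) / len(seq)
    assert np.all(np.abs(occ - 0.25) < 0.01)


# ---------------------------------------------------------------------------
# ideal intensities (unit-intensity algebra)


def test_ideal_intensities_basic():
    tr = ideal_intensities(np.array([0]), np.array([0.3]))
    assert tr.dd[0] == pytest.approx(0.7)
    assert tr.da[0] == pytest.approx(0.3)
    assert tr.aa[0] == pytest.approx(1.0)
    e, s = observed_es(tr)
    assert e[0] == pytest.approx(0.3)
    assert s[0] == pytest.approx(0.5)


@pytest.mark.parametrize("efret", [0.0, 0.25, 0.5, 0.9, 1.0])
def test_da_formula_inverts_fret_definition(efret):
    # -(DD*E)/(E-1) must reproduce DA such that DA/(DD+DA) == E
    tr = ideal_intensities(np.array([0]), np.array([efret]))
    assert tr.dd[0] + tr.da[0] == pytest.approx(1.0)
    e, _ = observed_es(tr)
    assert e[0] == pytest.approx(efret)


def test_conservation_on_live_frames(rng):
    # before artifacts, DD + DA == 1 exactly for a live smFRET pair
    cfg = _smfret_config(n_states=2, fret=[0.2, 0.8], trans_prob=0.1)
    seq = sample_state_sequence(cfg, 300, rng)
    tr = ideal_intensities(seq, cfg.fret_values)
    assert np.allclose(tr.dd + tr.da, 1.0)


# ---------------------------------------------------------------------------
# photophysics


def _smfret_config(n_states, fret, trans_prob, **kw):
    from fretsort.simulate import TraceConfig

    defaults = dict(
        trace_class="smFRET",
        n_states=n_states,
        fret_values=np.asarray(fret, dtype=float),
        trans_prob=trans_prob,
        noise_sigma=0.0,
        has_gamma_noise=False,
        aa_mismatch=1.0,
        bleedthrough=0.0,
        donor_bleach_frame=10**9,
        acceptor_bleach_frame=10**9,
        falloff_frame=None,
        blink_events=[],
        aggregate_size=None,
        scramble_mode=None,
        rng_seed=0,
    )
    defaults.update(kw)
    return TraceConfig(**defaults)


def test_acceptor_bleach_restores_donor(rng):
    params = SimulationParams()
    cfg = _smfret_config(1, [0.3], 0.0, acceptor_bleach_frame=100)
    seq = np.zeros(300, dtype=int)
    out, dark = apply_photophysics(
        ideal_intensities(seq, cfg.fret_values), cfg, params, rng
    )
    assert np.allclose(out.dd[:100], 0.7)
    assert np.allclose(out.dd[100:], 1.0)  # full donor recovery
    assert np.allclose(out.da[100:], 0.0)
    assert np.allclose(out.aa[100:], 0.0)
    _, s = observed_es(out)
    assert np.allclose(s[100:], 1.0)
    assert dark == 300  # donor never bleaches


def test_donor_bleach_keeps_acceptor_excitation(rng):
    params = SimulationParams()
    cfg = _smfret_config(1, [0.3], 0.0, donor_bleach_frame=50)
    out, _ = apply_photophysics(
        ideal_intensities(np.zeros(300, dtype=int), cfg.fret_values),
        cfg, params, rng,
    )
    assert np.allclose(out.dd[50:], 0.0)
    assert np.allclose(out.da[50:], 0.0)
    assert np.allclose(out.aa[50:], 1.0)  # direct excitation persists


def test_double_bleach_at_zero_gives_all_bleached(rng):
    params = SimulationParams()
    cfg = _smfret_config(
        1, [0.3], 0.0, donor_bleach_frame=0, acceptor_bleach_frame=0
    )
    out, dark = apply_photophysics(
        ideal_intensities(np.zeros(300, dtype=int), cfg.fret_values),
        cfg, params, rng,
    )
    assert np.allclose(out.channel_stack(), 0.0)
    assert dark == 0
    labels = label_frames(cfg, dark, np.zeros(300, dtype=int), params)
    assert all(c == "B" for c in labels.hard_symbols())


def test_aggregate_shows_multiple_bleach_steps(rng):
    params = SimulationParams(p_blink=0.0)
    cfg = _smfret_config(
        1, [0.3], 0.0, trace_class="aggregate", aggregate_size=3
    )
    out, _ = apply_photophysics(
        ideal_intensities(np.zeros(300, dtype=int), cfg.fret_values),
        cfg, params, rng,
    )
    # three pairs: starting intensity is three units across channels
    assert out.aa[0] == pytest.approx(3.0)
    # intensity can only step down as fluorophores die
    assert out.aa.max() == out.aa[0]


def test_blink_is_temporary(rng):
    params = SimulationParams()
    cfg = _smfret_config(
        1, [0.4], 0.0, blink_events=[(50, 10, "acceptor")]
    )
    out, _ = apply_photophysics(
        ideal_intensities(np.zeros(300, dtype=int), cfg.fret_values),
        cfg, params, rng,
    )
    assert np.allclose(out.da[50:60], 0.0)
    assert np.allclose(out.dd[50:60], 1.0)  # donor recovers during blink
    assert np.allclose(out.da[60:], 0.4)  # and transfer resumes after


# ---------------------------------------------------------------------------
# scrambling


def test_correlate_mode_replaces_channel_with_product(rng):
    # product-channel oracle: after scrambling, one channel must equal the
    # unit-rescaled product of two pre-scramble channels
    params = SimulationParams()
    cfg = _smfret_config(
        2, [0.2, 0.9], 0.15, trace_class="scrambled",
        scramble_mode="correlate",
    )
    seq = sample_state_sequence(cfg, 300, rng)
    tr = ideal_intensities(seq, cfg.fret_values)
    before = tr.channel_stack().copy()
    out, _ = apply_scramble(tr, cfg, params, rng)
    after = out.channel_stack()
    candidates = []
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            prod = before[:, i] * before[:, j]
            if prod.max() > 0:
                prod = prod / prod.max()
            candidates.append(prod)
    changed = [k for k in range(3) if not np.allclose(after[:, k], before[:, k])]
    # at most one channel is rewritten (a product involving constant AA = 1
    # can leave the trace unchanged, which is still the product rule)
    assert len(changed) <= 1
    for k in changed:
        assert any(np.allclose(after[:, k], c) for c in candidates)


def test_flip_of_constant_channel_is_identity(rng):
    params = SimulationParams()
    cfg = _smfret_config(
        1, [0.5], 0.0, trace_class="scrambled", scramble_mode="flip"
    )
    tr = ideal_intensities(np.zeros(100, dtype=int), cfg.fret_values)
    before = tr.channel_stack().copy()
    out, _ = apply_scramble(tr, cfg, params, rng)
    assert np.allclose(out.channel_stack(), before)


def test_miscolocalized_bleach_steps_independent():
    # donor and FRET channel come from different molecules, so their
    # bleach frames must be statistically independent
    params = SimulationParams(n_frames=300)
    rng = np.random.default_rng(7)
    dd_bleach, da_bleach = [], []
    for _ in range(400):
        cfg = _smfret_config(
            1, [0.5], 0.0, trace_class="scrambled",
            scramble_mode="miscolocalized",
        )
        tr = ideal_intensities(np.zeros(300, dtype=int), cfg.fret_values)
        out, _ = apply_scramble(tr, cfg, params, rng)
        dz = np.flatnonzero(out.dd <= 0)
        az = np.flatnonzero(out.da <= 0)
        dd_bleach.append(dz[0] if len(dz) else 300)
        da_bleach.append(az[0] if len(az) else 300)
    r = np.corrcoef(dd_bleach, da_bleach)[0, 1]
    assert abs(r) < 0.15


# ---------------------------------------------------------------------------
# detection artifacts


def test_artifacts_identity_when_disabled(rng):
    params = SimulationParams()
    cfg = _smfret_config(1, [0.3], 0.0, noise_sigma=0.0, aa_mismatch=1.0)
    tr = ideal_intensities(np.zeros(100, dtype=int), cfg.fret_values)
    before = tr.channel_stack().copy()
    out = add_detection_artifacts(tr, cfg, params, rng)
    assert np.allclose(out.channel_stack(), before)


def test_bleedthrough_leaks_donor_into_da(rng):
    params = SimulationParams()
    cfg = _smfret_config(1, [0.0], 0.0, noise_sigma=0.0, bleedthrough=0.15)
    tr = ideal_intensities(np.zeros(50, dtype=int), cfg.fret_values)
    out = add_detection_artifacts(tr, cfg, params, rng)
    assert np.allclose(out.da, 0.15)  # 15% of the unit donor signal


def test_noise_sd_matches_sigma(rng):
    params = SimulationParams()
    cfg = _smfret_config(1, [0.5], 0.0, noise_sigma=0.1, has_gamma_noise=False)
    seq = np.zeros(10_000, dtype=int)
    params10k = SimulationParams(n_frames=10_000)
    tr = ideal_intensities(seq, cfg.fret_values)
    out = add_detection_artifacts(tr, cfg, params10k, rng)
    resid = out.dd - tr.dd
    assert np.std(resid) == pytest.approx(0.1, rel=0.02)


def test_gamma_noise_is_centered_and_skewed(rng):
    from scipy import stats

    params = SimulationParams(n_frames=200_000)
    cfg = _smfret_config(1, [0.5], 0.0, noise_sigma=0.2, has_gamma_noise=True)
    tr = ideal_intensities(np.zeros(200_000, dtype=int), cfg.fret_values)
    out = add_detection_artifacts(tr, cfg, params, rng)
    resid = out.aa - tr.aa
    assert np.mean(resid) == pytest.approx(0.0, abs=0.005)
    assert stats.skew(resid) > 0.1  # gamma component skews right


# ---------------------------------------------------------------------------
# labels and balancing


def test_noisy_label_threshold():
    params = SimulationParams()
    cfg = _smfret_config(1, [0.5], 0.0, noise_sigma=0.26)
    labels = label_frames(cfg, 300, np.zeros(300, dtype=int), params)
    assert labels.hard_symbols()[0] == "N"
    cfg = _smfret_config(1, [0.5], 0.0, noise_sigma=0.24)
    labels = label_frames(cfg, 300, np.zeros(300, dtype=int), params)
    assert labels.hard_symbols()[0] == "S"


def test_label_smoothing_arithmetic():
    labels = FrameLabels.from_hard(np.array([4]), smoothing=0.05)
    row = labels.smoothed[0]
    assert row[4] == pytest.approx(0.95 + 0.05 / 6)  # 0.9583...
    others = np.delete(row, 4)
    assert np.allclose(others, 0.05 / 6)  # 0.00833...
    assert row.sum() == pytest.approx(1.0)


def test_transition_after_bleach_is_static():
    params = SimulationParams()
    cfg = _smfret_config(2, [0.2, 0.8], 0.1)
    seq = np.array([0] * 100 + [1] * 200)  # only transition at frame 100
    labels = label_frames(cfg, 50, seq, params)  # bleached before it
    assert labels.hard_symbols()[0] == "S"
    labels = label_frames(cfg, 200, seq, params)  # transition observed
    assert labels.hard_symbols()[0] == "D"


def test_first_frame_class_matches_full_simulation(rng, default_params):
    for _ in range(150):
        cfg = sample_trace_config(default_params, rng)
        lean = first_frame_class(cfg, default_params)
        full = simulate_trace(default_params, rng, config=cfg).first_frame_class
        assert lean == full


def test_balanced_undersampling_oracle(rng):
    classes = ["A"] * 10 + ["N"] * 20 + ["X"] * 30 + ["S"] * 40 + ["D"] * 50
    rng.shuffle(classes)
    idx = balanced_indices(classes, rng)
    assert len(idx) == 50
    kept = np.asarray(classes)[idx]
    for c in "ANXSD":
        assert np.sum(kept == c) == 10


def test_empty_dataset():
    ds = generate_dataset(0, SimulationParams(), seed=0)
    assert len(ds) == 0


def test_dataset_determinism(default_params):
    a = generate_dataset(60, default_params, seed=5)
    b = generate_dataset(60, default_params, seed=5)
    assert len(a) == len(b)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.trace.channel_stack(), tb.trace.channel_stack())
        assert np.array_equal(ta.labels.hard, tb.labels.hard)


def test_balanced_dataset_has_equal_classes(small_dataset):
    counts = small_dataset.class_counts()
    nonzero = {c: n for c, n in counts.items() if c != "B"}
    assert counts["B"] == 0
    assert len(set(nonzero.values())) == 1


# ---------------------------------------------------------------------------
# observed E/S edge cases


def test_observed_es_undefined_markers():
    tr = Trace(dd=[0.0, 1.0], da=[0.0, 0.0], aa=[0.0, 0.0])
    e, s = observed_es(tr)
    assert np.isnan(e[0]) and np.isnan(s[0])
    assert e[1] == 0.0 and s[1] == 1.0  # post acceptor-bleach signature


def test_observed_s_undefined_for_non_alex():
    tr = Trace(dd=[0.5, 0.5], da=[0.5, 0.5])
    _, s = observed_es(tr)
    assert np.all(np.isnan(s))
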