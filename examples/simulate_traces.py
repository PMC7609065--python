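"""Generate a balanced ground-truth dataset and inspect its composition.

Simulates smFRET traces from the full generative model (Markov FRET
dynamics, photobleaching, blinking, aggregates, scrambles, detection noise),
under-samples to balance the five non-bleached first-frame classes, and
writes a few traces as plain-text files.
"""

from pathlib import Path

from fretsort import SimulationParams, generate_dataset, observed_es
from fretsort.io import write_traces

params = SimulationParams()  # training priors: see docs/methods.md
dataset = generate_dataset(1000, params, seed=42)

print(f"simulated 1000 traces -> {len(dataset)} after class balancing")
print("first-frame class counts:", dataset.class_counts())

lt = next(t for t in dataset if t.first_frame_class == "D")
e, s = observed_es(lt.trace)
cfg = lt.config
print(
    f"\nexample dynamic trace: {cfg.n_states} states at "
    + ", ".join(f"{v:.2f}" for v in sorted(cfg.fret_values))
    + f"; per-frame transition probability {cfg.trans_prob:.3f}"
)
print(f"noise sigma {cfg.noise_sigma:.3f}; "
      f"donor bleach frame {cfg.donor_bleach_frame}, "
      f"acceptor bleach frame {cfg.acceptor_bleach_frame}")

out = Path("scratch/example_traces")
written = write_traces(dataset.traces[:5], out, include_labels=True)
print(f"\nwrote {len(written)} ASCII trace files under {out}/")
print("each row: frame DD DA AA label  (label in B/A/N/X/S/D)")
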