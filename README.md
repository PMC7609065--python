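# fretsort

Simulation, per-frame deep classification, confidence-score sorting and
kinetic analysis of single-molecule FRET (smFRET) time traces.

## The problem

smFRET with TIRF microscopy reports nanometer-scale distances in single
biomolecules through three background-corrected intensity channels — DD
(donor excitation, donor emission), DA (donor excitation, acceptor
emission) and, with alternating laser excitation (ALEX), AA (acceptor
excitation, acceptor emission) — from which each frame's FRET efficiency
`E = DA / (DD + DA)` and stoichiometry `S = (DD + DA) / (DD + DA + AA)`
follow. A raw experiment yields thousands of traces of which only a small
fraction are usable single molecules; the rest are aggregates, incompletely
labeled or wrongly colocalized molecules, and noise. Selecting the good
traces by hand is slow and subjective, and simple thresholds on median
stoichiometry and intensity cannot separate artifacts that statistically
mimic real molecules.

`fretsort` addresses this with a classifier trained purely on simulated
ground truth:

* a **generative simulator** produces labeled traces spanning 1–4 FRET
  states (uniform on [0, 1], minimum separation 0.1), Markov dynamics
  (per-destination transition probability up to 0.2 per frame), exponential
  photobleaching (mean 500 frames), blinking, fall-off, aggregates,
  scrambled artifacts, acceptor mismatch, donor bleedthrough, and
  Gaussian-plus-centered-Gamma detector noise;
* a **residual-convolutional + bidirectional-LSTM network** (NumPy
  implementation, `fretsort.nn`) labels every frame with six softmax
  probabilities: bleached (B), aggregate (A), noisy (N), scrambled (X),
  static smFRET (S), dynamic smFRET (D);
* a **confidence score** per trace — bleached frames are cut by a 4-of-7
  sliding window on p(B), the remaining per-frame probabilities are
  averaged and renormalized into five category scores, and
  `confidence = P_S + P_D` — turns sorting into a single user threshold
  (0.85 recommended);
* a **baseline threshold sorter** (median stoichiometry, max intensity,
  bleaching) quantifies what the classifier improves on;
* **kinetics**: Gaussian-emission HMM idealization (Baum–Welch via
  hmmlearn), BIC state-count selection, dwell-time/lifetime fits and
  transition-density statistics.

See `docs/methods.md` for the full model description and
`examples/` for narrative scripts (simulation, baseline sorting,
classification, kinetics).

## Worked example

`python examples/kinetics_analysis.py` simulates 30 two-state smFRET
traces (FRET 0.3/0.7, per-frame transition probability 0.1, sigma 0.05),
truncates each at its first bleach via the stoichiometry window, selects
the state count by BIC and fits the kinetics:

```
idealized 21 traces; BIC state counts: [ 0 21  0  0]  (index = K)
recovered state means: [0.325 0.704] (truth 0.3 / 0.7)
state 0: lifetime 8.2 frames (95% CI 6.7-9.7, n=115 uncensored dwells; truth 10 frames)
state 1: lifetime 8.6 frames (95% CI 7.0-10.1, n=117 uncensored dwells; truth 10 frames)
transitions observed: 232
```

Every trace gets the correct two-state model; the state means land within
0.03 of the ground truth, and the dwell lifetimes recover the simulated
10-frame mean with the mild downward bias expected from Viterbi
fragmentation of short dwells.

`python examples/baseline_sorting.py` shows the flip side: on a mix of 100
true smFRET and 1000 artifact traces, the best simple-threshold grid point
reaches precision 0.295 at recall 0.440 — and precision drops further as
the artifact pool grows relative to the true population (≈0.15 at the
200 + 5000 benchmark scale). That failure mode is the motivation for
score-based sorting.

## Command line

A thin CLI wraps the library:

```bash
fretsort simulate --n 1000 --seed 1 --out traces/
fretsort train --data traces/ --seed 1 --out model.npz --res-blocks 4 --base-filters 16
fretsort predict --model model.npz --traces traces/ --out probs.txt
fretsort score --model model.npz --traces traces/ --threshold 0.85 --out decisions.csv
fretsort sort --traces traces/ --int-lo 0.5 --int-hi 1.6 --out sorted.csv
fretsort analyze --traces accepted/ --kmax 4 --obs fret --out results/
```

Every command takes `--seed`; identical seed and configuration reproduce
outputs bit for bit.

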