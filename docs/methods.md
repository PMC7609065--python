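# Methods

`fretsort` couples a generative simulator for single-molecule FRET (smFRET)
fluorescence time traces to a per-frame deep sequence classifier, a
confidence-score acceptance rule, a baseline threshold sorter for
comparison, and hidden-Markov kinetic analysis. This note documents the
model, its parameters and defaults, the numerical choices, and what the
synthetic data does and does not establish.

## Generative model for smFRET traces

A trace is 300 frames of three background-corrected intensities recorded
under alternating laser excitation (ALEX): donor-excited donor emission
(DD), donor-excited acceptor emission (DA) and acceptor-excited acceptor
emission (AA). All intensities are expressed in units of one fluorophore's
emission, so a single intact molecule peaks near 1.

**FRET dynamics.** Each molecule carries 1–4 FRET states drawn uniformly on
[0, 1] by rejection until every pair of states is at least 0.1 apart (below
that separation, transitions are indistinguishable from noise). State
dynamics follow a discrete-time Markov chain: at every frame the molecule
jumps to each of the other `n − 1` states with a per-destination
probability drawn once per trace from Uniform(0, 0.2); with four states the
total leave probability can reach 0.6, i.e. a 0.4 probability of staying.
Because the destination given a jump is uniform over the other states, the
chain is simulated without a frame loop (cumulative sum of random nonzero
offsets modulo `n`), and its stationary distribution is uniform — the
transition-density plot of the training population is unbiased by
construction (tested).

**Ideal intensities.** With unit total emission, `DD = 1 − E` and inverting
`E = DA/(DD + DA)` gives `DA = −(DD·E)/(E − 1)`, which algebraically equals
`E` (the `E = 1` limit is handled explicitly). `AA = 1` regardless of the
FRET state, so ideal stoichiometry `S = (DD + DA)/(DD + DA + AA)` is
exactly 0.5, and `DD + DA = 1` on every live frame (exact; tested as a
conservation law).

**Photophysics.** Donor and acceptor bleach independently at integer frames
drawn from an exponential with mean 500 frames — most traces bleach inside
the 300-frame window, a sizable minority never do. Donor-dark frames
(bleach or blink) zero DD and DA while AA persists (the acceptor is still
directly excited); acceptor-dark frames zero DA and AA while the donor
*recovers its full unit intensity* (no more energy transfer — standard FRET
photophysics; the source description only states which channels are
zeroed). With probability 0.1 the molecule falls off the surface at an
Exp(500) frame, zeroing everything. Blinking affects 20% of non-aggregate
traces: a Poisson(1) number of events, each darkening one fluorophore for
1 + Exp(5) frames — short enough that blinking is not confounded with
bleaching. Blinking kinetics are a package choice; the source gives none.

**Aggregates** (15% of traces) are spots containing several labeled
molecules: a uniform 2–10 independent donor/acceptor pairs, each with its
own state sequence and bleach times, summed. The uniform size law and the
independent dynamics are package choices ("any given size" is all the
source states); intensities are rescaled only by the per-trace max
normalization of the model input, so multi-step bleaching and
super-unitary intensity survive as features.

**Scrambled traces** (15%) train the classifier to reject aberrant data and
are deliberately non-physical. One elementary transformation is always
applied — time-reversing one channel, replacing a channel by the
unit-rescaled product of two channels, overwriting random segments with
high-amplitude noise bursts, or zeroing long random segments — and with
probability 0.9 the source channels additionally come from two independent
molecules (DD from one, DA/AA from the other), emulating incorrect
colocalization. "Flipping" is implemented as time reversal; amplitude
inversion was considered and rejected since time reversal already breaks
the donor/acceptor anticorrelation without leaving negative intensities.

**Detection artifacts.** AA is scaled by an acceptor-only mismatch drawn
from Uniform(0.70, 1.30); a donor bleedthrough fraction Uniform(0, 0.15) of
DD leaks into DA. Per-frame noise is Normal(0, σ) with σ ~ Uniform(0.01,
0.30) (σ in units of the maximum single-fluorophore intensity), added to
every channel including bleached frames (detector readout). With
probability 0.8 a skewed component is added: a Gamma(k = 1, θ = 1.1) draw
minus its mean 1.1, multiplied by σ — "centered" is read as
mean-subtracted, so the component is zero-mean but right-skewed, mimicking
shot noise.

**Labels.** Every frame receives one of six classes: frames at/after the
all-dark frame (both fluorophores bleached, or fall-off) are `B` bleached;
live frames are `A` aggregate or `X` scrambled by trace class, else `N`
noisy when σ > 0.25, else `D` dynamic if any state transition falls inside
the observed pre-bleach window and `S` static otherwise (staticness is
defined *within the experimental time frame*: a two-state molecule whose
only transition falls after bleaching is static). `A`/`X` take precedence
over `N` — an aggregate stays an aggregate however noisy. The 0.25 noisy
threshold is the point beyond which a normality test can no longer support
mixture-model state fitting. Targets are label-smoothed,
`(1 − ε)·onehot + ε/6` with ε = 0.05 (so the true class gets 0.9583…, every
other 0.00833…).

**Balancing.** Datasets are generated by simulating `n` traces and
under-sampling on the first-frame label: traces bleached from frame 0 are
dropped, and the five non-bleached classes are randomly down-sampled to the
rarest class's count. At the default priors the rarest class is `N`
(0.7 × P(σ > 0.25) ≈ 12.1% of traces), so 250,000 initial traces retain
≈ 151,000 — balancing, not an explicit target, sets that number. Per-trace
seeds are spawned from the dataset seed by counter, so generation is
deterministic and parallelizable; `balanced_count_stream` computes
first-frame labels without synthesizing intensities for memory-bounded
balancing runs at any scale (its agreement with the full pipeline is
tested).

## Per-frame classifier

The network maps a normalized trace (T × 3 channels for ALEX, T × 2
without AA) to T × 6 row-stochastic class probabilities. Normalization
divides all channels by the single global maximum over channels and frames,
preserving relative intensities and removing instrument units.

Architecture: an initial convolution (same hyperparameters as the first
residual block), then a stack of residual blocks — block `j` uses
`32 · 2^(j div 4)` filters and kernel `16 − 4·(j div 4)` (floored at 4), so
early blocks see large-scale features and deep blocks small ones; each
block is Conv(k) → BatchNorm → ReLU → Conv(1×1) → BatchNorm plus an
identity shortcut (1×1-projected when the filter count changes), ReLU, and
stride-1 max pooling (length-preserving: the output is per-frame). The
1×1 convolution is read as a bottleneck/projection added for efficiency;
batch normalization sits before each activation. After the convolutional
stack, a 16-unit bidirectional LSTM (dropout 0.4 on its outputs) propagates
evidence such as early multi-step bleaching across the whole trace, and a
time-distributed dense layer produces the six softmax logits. The default
depth is 16 blocks, at which the kernel schedule 16 → 4 completes exactly;
depth and width are configurable (`ModelSpec`).

Training: cross-entropy against the smoothed targets, Adam at learning
rate 0.001 in batches of 32, He initialization for convolutions, 80/20
train/validation split, learning rate divided by 10 after two epochs
without validation improvement, early stopping after five with the best
weights restored. The whole stack — layers, backpropagation (including
backpropagation through time for the LSTM), Adam, the schedules — is
implemented in NumPy in `fretsort.nn`; arithmetic is float32 (float64 is
used for the numerical gradient check in the test suite, which verifies
every layer's analytic gradient to ~1e-6 relative error). On CPU the run
is bit-deterministic for a fixed seed.

## Confidence score and acceptance

From the per-frame probabilities, bleaching is detected with a sliding
window: the first frame index whose 7-frame window (truncated windows at
the trace end still need the full quota) contains ≥ 4 frames with
p(B) > 0.5 marks the bleach start — a single confidently "bleached" frame
cannot truncate a trace. Frames from the bleach start onward are excluded;
the five non-bleached class probabilities are summed over live frames and
renormalized to sum to one, giving per-trace category scores P_A, P_N,
P_X, P_S, P_D. The renormalized form is preferred over a plain average
because it is insensitive to the small p(B) mass on live frames; the two
coincide otherwise. The smFRET confidence score is P_S + P_D (both static
and dynamic molecules are usable data). If bleaching strikes before frame
15, the trace is classified bleached outright with confidence 0 — scoring
a handful of frames would inflate the confidence. A trace is accepted when
its confidence is ≥ the user threshold (inclusive); 0.85 is the
recommended default, trading precision against recall. The assigned class
is the argmax of the five scores.

## Baseline threshold sorter

The comparison baseline emulates common manual practice on ALEX data:
frames are marked bleached by the same 4-of-7 window applied to
stoichiometry outside (0.3, 0.7) (undefined S counts as outside); a trace
is accepted iff bleaching is present, the median live-frame S lies in
(0.3, 0.7), and the maximum live-frame single-molecule intensity — the
total donor-excited emission DD + DA — falls inside configurable bounds.
Anticorrelation is deliberately not used (it presumes all molecules are
dynamic). Since published threshold values vary, the benchmark sweeps a
coarse tight-to-loose 3×3 grid of intensity bounds (lower 0.3/0.6/0.9,
upper 1.3/1.6/2.0 in single-fluorophore units) and reports the best
precision over the grid with its recall.

The mixed-population experiment draws 200 ground-truth two-state
(FRET 0.3/0.7, transition probability 0.1) smFRET traces at σ = 0.11 and
5% bleedthrough — ground-truth traces that never bleach are discarded and
resampled — and hides them among 5000 artifact traces drawn at the full
training priors (so genuinely too-noisy traces are represented alongside
aggregates and scrambles). One- and three-state variants (0.5; 0.2/0.5/0.8)
are available through the same entry point.

## Kinetics

Accepted traces are idealized per trace with a Gaussian-emission HMM fit by
Baum–Welch (hmmlearn), observing either the 1-D FRET efficiency series or
the 2-D (DD, DA) channels. Initialization is deterministic:
quantile-spaced means, uniform start probabilities, a diagonally dominant
transition matrix (0.95 stay), covariance floored at 1e-4. The state path
is the Viterbi path; states are relabeled in ascending FRET order. The
number of states is chosen by minimizing
`BIC = −2 log L + k ln(n)` over K = 1..4 with
`k = K(K−1) + K + K + (K−1)` free parameters (transitions, means,
variances, start probabilities); ties break toward fewer states. Per-trace
fitting (rather than a global shared-parameter HMM) matches how the traces
are selected one at a time; a global fit is a possible extension. Dwells
are the constant-state segments of the path; each trace's final dwell is
censored (its end is unobserved) and excluded from the per-state
exponential lifetime fit (MLE mean with a normal-approximation 95% CI).
The transition-density plot is the 2-D histogram of (state FRET before,
state FRET after) over all observed transitions. A user-supplied
multiplicative γ / crosstalk correction can be applied to E before
fitting; estimating such correction factors is out of scope.

## Problem sizes in the test suite

The distribution checks use 10,000 sampled configurations (bleach-time
mean, class priors, FRET-marginal Kolmogorov–Smirnov against a brute-force
rejection reference) and 1,000 dynamic traces (transition-density
uniformity). The balancing check streams 250,000 traces through the lean
first-frame-label path. The sorting benchmark averages five replicate
200 + 5000 mixes. The classifier check trains the reduced architecture
(4 residual blocks, 16 base filters, doubling every 2 blocks) on ≈ 6,000
balanced traces of 300 frames for up to 30 epochs and evaluates ≈ 500
held-out traces; these sizes are the package's desk-scale defaults, chosen
so the whole suite runs on one CPU in well under half an hour. HMM
parameter recovery uses 100 simulated two-state traces at σ = 0.05.

## What the synthetic data does not emulate

Camera physics (EMCCD gain, pixelation, point-spread rendering), raw image
analysis and colocalization, diffusing particles, 3/4-color FRET, and
correction-factor estimation are all outside the generative model. Noise
is stationary within a trace; real data can drift. Aggregate pairs are
kinetically independent; physically coupled aggregates are not modeled.
Blinking kinetics and the aggregate size law are plausible choices, not
measurements. Consequently, passing tests demonstrate that the classifier
and kinetics recover the *simulated* ground truth under these priors; on
real data the classifier's usefulness rests on the priors spanning the
behaviors the instrument produces, and users with atypical conditions
should retrain on adjusted priors (`SimulationParams` is fully
user-settable).
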