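# Methods

This note documents the model implemented by `hrmas`, the parameter
choices that matter, what the synthetic tasks do and do not emulate, the
numerical decisions, and the limitations we have measured. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Neuron and synapse model

Dynamics are simulated with a fixed-step first-order Euler scheme at 1 ms
per step; every time constant below is in steps, so millisecond values
divide through directly. Each neuron carries

* a postsynaptic-current (PSC) trace, a first-order low-pass filter of its
  spike train: `a[t] = (1 − 1/τ_syn)·a[t−1] + s[t]`. A lone spike decays
  as `(1 − 1/τ_syn)^Δt` and the impulse response sums to `τ_syn`;
* a leaky membrane `u⁻[t] = (1 − 1/τ_m)·u[t−1] + (R/τ_m)·I[t]`, where
  `I[t]` is the summed weighted PSC drive. Spike and reset co-occur at
  `u⁻ ≥ v_th` (the indicator and the reset branch can never disagree;
  exact float equality at threshold is measure-zero), and the reset is to
  zero. No refractory period, normalization, or dropout.

Feedforward connections act with zero delay; recurrent connections carry a
one-step delay. Initial conditions are rest (`u = a = 0`).

Defaults: `τ_m = 16`, `τ_syn = 8` (speech-scale values widely used for
this neuron model), `R = 1`. The firing threshold is a per-layer tunable;
the desk-scale default is `v_th = 0.3` because with He-Normal feedforward
weights and the `1/τ_m` membrane gain, a threshold of 1 leaves a 16–32
neuron network silent and all surrogate gradients vanishingly small.

## The motif layer

A hidden layer of `n` neurons is partitioned into motifs of size `v`.
Candidate recurrent connections are (i) every directed pair within a
motif, self-loops included, and (ii) mutual links between corresponding
neurons of the two adjacent motifs (truncated at the layer edges; no
wrap-around). This yields `(n/v)·v²` intra plus `2(n−v)` inter candidate
slots — linear in `n` at fixed `v`. Each slot takes one of three types:
excitatory (weight trainable, initialized to 0.2), inhibitory (weight
fixed and negative), or non-existent.

Motifs share one topology template by default (`tying="shared_topology"`):
type choices are indexed by relative position `(i mod v, r mod v)` for
intra slots and by direction `±v` for inter slots. An `untied` mode gives
every slot its own logits. Synaptic weights are untied per connection in
both modes.

**Inhibitory magnitude.** The inhibitory weight is fixed (never trained,
never searched); the conventional value −2 is kept as the default and in
the large-layer presets. For desk-scale layers (n ≈ 16–32) we use −0.5 in
the experiments: the candidate inhibitory in-degree per neuron is an order
of magnitude larger *relative to layer size* than in an 800-neuron layer
with 2-neuron motifs, and we measured that retraining identical searched
architectures with −2 versus −0.5 moves test accuracy from ~0.7 to ~0.9 —
full-strength inhibition at that in-degree silences the layer.

## Relaxation and search

Motif size (over a finite option set `V`) and per-slot types are relaxed
by softmax distributions over logits; the recurrent drive becomes the
probability-weighted mixture over all options, which makes the
architecture differentiable end to end. Training alternates two steps per
iteration:

1. **Gradient step.** One bi-level update of the architecture logits —
   validation-loss gradient at one-step-look-ahead weights
   `w' = w − η·∇_w L_train`, minus the curvature correction
   `η/(2ε)·[∇_α L_train(w+) − ∇_α L_train(w−)]` with
   `w± = w ± ε·∇_w L_valid(w')` — followed by one Adam update of all
   weights on the training split. With `η = 0` the update reduces exactly
   to the first-order validation gradient.
2. **Intrinsic-plasticity window.** One mini-batch is presented while the
   homeostatic rule (below) adapts each recurrent neuron's `R` and `τ_m`
   online; the adapted values are what the next iteration's gradients see.

The schedule is staged: motif size and types are searched jointly in
stage 1; at the boundary the motif size is frozen by argmax of its relaxed
probabilities (irreversibly); stage 2 continues on types only. The final
architecture takes the argmax type per slot (ties resolve to the lowest
index, i.e. excitatory), is retrained from scratch — all weights
reinitialized: He-Normal feedforward, 0.2 excitatory recurrent — on the
full training set, and is evaluated exactly once on the held-out test set.

Backpropagation through time is exact over the full horizon (no
truncation) and is written directly in NumPy. The spike nonlinearity's
derivative is a pluggable surrogate kernel (default: the logistic-derivative
bump, peak at `v_th`, unit integral; triangle and Gaussian kernels are
selectable). In `spike_mode="smooth"` the forward pass uses the matching
soft spike, making the computed gradients the *exact* gradients of that
relaxed graph — this is how the implementation is validated: weight and
architecture-logit gradients against central finite differences
(rel. err < 1e-4 on all toys), and the bi-level curvature term against a
complex-step (forward-over-reverse) oracle, to which it converges at
O(ε²).

**Learning rates.** Weights use Adam at 5e-3 (desk) or 5e-4 (large-layer
presets). Architecture logits use Adam at 1e-2 at desk scale — sized so
logits can traverse O(1) within a 120-iteration stage; an α rate an order
of magnitude below the weight rate leaves the relaxed probabilities
effectively at initialization, and the "searched" architecture is then an
argmax over noise (we measured such architectures to be statistically
indistinguishable from unselected random ones). `η` (inner look-ahead
rate) defaults to the weight rate; `ε` defaults to 1e-2.

## Intrinsic plasticity

Each recurrent neuron estimates its firing rate from an intracellular
calcium trace, `ϕ[t] = (1 − 1/τ_cal)·ϕ[t−1] + s[t]`, `y = ϕ/τ_cal`
(`τ_cal = 16`). The adaptation minimizes the KL divergence from the
neuron's output-rate distribution to an exponential distribution with mean
`μ`: for the closed-form LIF rate under constant current,
`y(x; R, τ) = 1/(τ·ln(Rx/(Rx − v_th)))`, the instantaneous objective is
`L_IP = −ln(∂y/∂x) + y/μ` (output-entropy maximization plus mean-rate
penalty), and both intrinsic parameters descend its exact gradient:

```
∂L/∂τ = (1 − y/μ)/τ
∂L/∂R = (z − 2·v_th·τ·y + v_th·τ·y²/μ) / (R·(z − v_th)),   z = Rx
```

with the operating point implied from the measured rate,
`z − v_th = v_th/(e^{1/(τy)} − 1)`. The `τ` update vanishes exactly at
`y = μ`, which is the mechanism that drives the long-run rate to the
target; the `R` update maximizes transfer sensitivity and, in closed loop,
drifts toward its clamp while `τ` holds the rate. Guards: a rate floor of
1e-4, a ceiling of 30 on the exponent `1/(τy)`, per-step update clipping
at magnitude 10, and clamps `R ∈ [0.2, 10]`, `τ ∈ [2, 256]`. The lower
`R` clamp is 0.2 rather than a smaller value because the adapted operating
point sits near `R_min·I`; with a smaller clamp, drives weak enough to
show meaningful fixed-parameter rate variation fall below rheobase after
adaptation.

Defaults `μ = 0.1` spikes/step and `γ = 0.4`. These follow from the
closed-loop relaxation analysis: the equilibrium time constant of the `τ`
loop is ≈ `τ*²/γ` steps with `τ* ≈ z/μ`, so smaller `μ` or `γ` pushes
convergence beyond any practical horizon; with these values the
homeostasis sweep (constant drives spanning 10×, five seeds of random
amplitudes) lands within 10% of `μ` after 150,000 adaptation steps, which
the acceptance suite verifies. IP runs on recurrent neurons only, during
the search phase; it is off in phase-2 retraining (a flag enables it).
With a batch, the calcium trace advances with the batch-mean spike
indicator — equivalent to averaging the per-sample updates.

## Synthetic tasks

* **Pattern task** — one random spatiotemporal template per class,
  Gaussian time-jitter, optional Poisson background. Difficulty grows with
  jitter (verified as a monotone accuracy trend). Note: this task is
  essentially spatial; a feedforward spiking network solves it at ceiling,
  so it cannot rank recurrent architectures.
* **Temporal-order task** — three input populations fire bursts in a
  class-specific order with gaps of ~2 synaptic time constants;
  time-summed channel counts are class-independent (asserted in the test
  suite), so an accumulated-PSC feedforward readout is nearly order-blind
  and recurrent memory genuinely pays (measured: 0.86 feedforward vs ~0.95
  for good recurrent architectures). This is the ablation benchmark.
* **Teacher task** — a random discrete motif network with a planted motif
  size labels Poisson input by its readout argmax; degenerate label draws
  (any class under 10%) are rejected and redrawn. The teacher scores 1.0
  on its own dataset by construction.

None of these emulate real sensory statistics (cochleagram channel
correlations, event-camera polarity structure, long non-stationary
recordings), so passing results demonstrate correctness and qualitative
behavior of the machinery, not expected accuracy on real benchmarks.

## Known limitations (measured)

* **Motif-size selection at desk scale.** For nested option sets (every
  2-periodic tied template is also 8-periodic, so the `v = 2` candidate
  set is contained in the `v = 8` set up to a handful of
  boundary-crossing lateral links), the relaxed bi-level credit
  consistently favors the *largest* motif size, independent of the data:
  we measured identical selections on planted-2, planted-8 and
  random-label teacher tasks, under warm-started weights, sparse type
  initializations, quiet readout initializations, and overfitting-sized
  training subsets. The planted wiring does imprint on the recurrent
  weight *gradients* (≈5× on-band concentration) but that signal does not
  reach the motif-size logits. The planted-size recovery experiment is
  therefore expected to fail at this scale, and the acceptance suite
  reports it honestly rather than weakening the check. This mirrors the
  documented co-adaptation/largest-option pathology of
  differentiable-relaxation architecture search.
* **Gradient search vs. random search at desk scale.** With a matched
  compute budget, random sampling of discrete architectures with
  validation-based selection scores ~2 points higher mean test accuracy
  than the gradient search on the order benchmark (the test suite runs
  this comparison). The with-IP ≥ without-IP ordering does hold. Random
  search being a strong baseline for relaxation-based architecture search
  at small scale is a well-documented phenomenon; we report it rather
  than tune around it.
* The IP rule's `R` dynamics have no interior fixed point jointly with the
  rate constraint; `R` rides its clamp in long closed-loop runs. Rate
  control is carried by `τ`.
* Silent neurons (rate at the floor) receive a degenerate IP update
  direction; clipping and clamps keep it bounded, but IP cannot rescue a
  neuron whose drive is subthreshold at maximum excitability.

## Problem sizes

Unit and acceptance tests use layers of 2–32 neurons, 30–60 timesteps,
200–300-sample datasets, 90–240 search iterations, and 150,000-step
homeostasis runs; the full suite and the acceptance script each complete
in a few minutes on one CPU. These sizes are the package's reference
conditions for the synthetic studies; the `ti46-alpha` and `n-tidigits`
presets carry the published large-layer hyperparameters for users with
the corresponding datasets.
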