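# Methods

This note documents the models, the training and evaluation protocol, the
synthetic ground-truth generator, and the numerical choices made where the
design was genuinely open.

## Encoding models

Every architecture is a causal, differentiable map `R^{F×T} → R^{N×T}`.
Causality is enforced structurally: all temporal windows read only past
bins, the stimulus is left zero-padded so output length equals input
length, and recurrent state flows strictly forward.  The test suite
verifies causality for every architecture by input perturbation.

Temporal-lag convention: weight tensors store lags oldest-to-newest, so the
last lag column acts on the current bin.  GradMaps and energy traces index
latency the other way around: latency 0 is the loss bin, latency τ is τ
bins in the past.

* **linear / ln** — per-neuron `F×W` STRF weights and a bias; `ln` adds the
  double-exponential output.  An optional input batch norm (one
  scale/offset per frequency band) is available and collapses to an affine
  map after training.
* **nrf** — a bank of `H` spectro-temporal filters → batch norm → sigmoid →
  linear readout → double exponential.
* **dnet** — the NRF topology with a fixed 5-bin input window whose hidden
  units are leaky integrators `h_t = (1−λ)h_{t−1} + λ·σ(BN(conv))`, with a
  per-unit leak `λ = σ(raw) ∈ (0,1)` learned jointly.
* **cnn2d** — stacked 2-D convolutions over (frequency, time); 'same'
  padding in frequency, causal left padding in time; BN + sigmoid after
  each; dense readout over (channel, frequency) per bin.  Defaults: 2
  layers, 3×3 kernels, 10 channels — configurable, since published 2-D CNN
  encoders differ in depth.
* **transformer** — per-bin frequency-vector tokens over a `W`-bin window,
  linear embedding (E = 48) plus learned positional embeddings, one
  post-LN encoder layer with 4 heads and a 4E feed-forward, mean pooling
  over tokens, linear readout, double exponential.
* **statenet** — locally connected (LC) frequency downsampling → BN → one
  recurrent core → linear readout from the state vector.  The LC layer has
  convolution-like receptive fields but position-specific weights
  (tonotopy without weight sharing); frequency ends are zero-padded so the
  number of positions is `ceil(F/stride)`.  Cores: Elman, GRU, LSTM
  (standard gate equations), and a diagonal state-space core: continuous
  `x' = Ax + Bu`, `y = Cx + Du` with `A = −exp(a_log)` (stable by
  construction) discretized by zero-order hold with a per-channel learned
  step, followed by a tanh.  The readout is linear by default; the
  double-exponential output can be switched on per spec.

The double exponential `f(x) = a·exp(−exp(kx−s)) + b` is implemented
exactly as written, with the inner exponent clamped to ±30 before
exponentiation to guard overflow.  No sign constraints are placed on
`(a, k)` so a fit can recover either response orientation.

## Differentiation and batch normalization

All forward code is written against `autograd.numpy`, and one reverse-mode
graph serves both training (gradients w.r.t. parameters) and
interpretation (gradients w.r.t. the input).  Gradients of every
architecture are checked against central finite differences.

Batch normalization uses a *refresh-then-freeze* scheme: each training
epoch begins by recomputing the per-channel running statistics from the
training set with the current parameters (a plain forward pass), and every
differentiated pass then normalizes with those frozen statistics.  The
learnable scale and offset remain in the graph.  Consequences: training is
deterministic given the seeds, full-BPTT and TBPTT gradients are computed
on identical footing, evaluation-time behaviour equals training-time
behaviour, and after training BN is a fixed affine map that can be absorbed
into neighbouring weights (verified by test).

## Training protocol

MSE between predicted rates and the PSTH, averaged over all `N·T` bins.
Adam with betas (0.9, 0.999) and a constant learning rate (default 1e-3);
no weight decay, dropout, or augmentation.  Whole clips are the training
unit (batch size in clips, default 1); an epoch is one seeded-shuffled pass
over the training clips.  After each epoch the model is validated; it is
checkpointed whenever validation loss improves and stopped after `patience`
(default 50) epochs without improvement, optionally capped by
`max_epochs`.  Each training seed draws its own clip-level 70–10–20 split
(rounded, every subset non-empty) and its own initialization.

TBPTT(K1=1, K2=K): the loss is evaluated at every bin, and the gradient of
the loss at bin `t` flows through at most `K` bins of history.  With
warmup the state entering each truncated graph is the state obtained by
running the network without gradients from the sequence start; without
warmup it is the zero state.  For bins `t < K` the graph starts at the
sequence start in both modes.  Implementation: the per-bin truncated
segments are batched — K masked recurrent steps over a `(batch·T)`-wide
segment batch — so the cost is `O(K)` python-level steps per update rather
than `O(T·K)`.  TBPTT(K=T, warmup) reproduces full-BPTT parameter
gradients to ~1e-16 (tested).

## Evaluation metrics

`CC_raw` is the Pearson correlation along time between prediction and
PSTH.  `CC_norm` replaces `Var(r)` with the signal-power estimate
`SP = [Var(Σ_m r_m) − Σ_m Var(r_m)]/(M(M−1))`.  All variances are
population variances (divide by count), which makes the identical-trials
identity `SP = Var(r)` exact.  Conventions: one trial ⇒ `CC_norm =
CC_raw`; non-positive SP or a zero-variance series ⇒ 0 with a warning
("zero variance" is assessed with a relative tolerance, since floating
arithmetic leaves ~1e-35 of variance on constant series).  Metrics are
computed after concatenating a split's clips into one long sequence; when
trial counts differ across clips, trials are truncated to the smallest
count for the concatenation.

## Interpretation

GradMaps evaluate `∂L/∂x` at the all-zero probe with
`L = −mean_{n∈targets} r̂_n[T]`; BN layers use their frozen statistics, so
a map is a property of the frozen model.  Dreams iterate Adam (default,
lr 1e-2 — the optimizer family is fixed but the step size is a free
choice exposed in the API) or plain gradient descent from the zero
stimulus, by default for 1500 iterations; an alternative stopping rule
("loss convergence": relative change below 1e-4 over 50 iterations,
capped at 1500) serves the dream-length curves.  Plain Dreams are
unconstrained by default; the dream-length curves project each update onto
the non-negative orthant (`clip_min=0`), because cochleagrams are
non-negative and unconstrained ascent drives gated recurrent cores into
gate saturation with out-of-range inputs, flattening the length dependence
the curve is meant to measure.  Energy
is the per-latency mean of squared map entries; similarity between models
is the Pearson correlation of flattened per-neuron maps averaged across
neurons (computed at a horizon slightly above the largest stateless
window, default 50 bins, so untouched zero bins do not inflate the
correlation).  Gradients for stateful models always use full unrolling
over the probe length, regardless of how the model was trained.

## Synthetic ground truth

The generator emulates the statistics that matter for encoding-model
benchmarks, not the audio itself:

* **Stimuli** — Gaussian white noise smoothed along frequency and time
  (default scales 0.7 bins each), standardized, then softplus-compressed:
  smooth, non-negative, log-compressed-like cochleagrams.  The default
  smoothness is deliberately modest: heavier smoothing makes the lagged
  stimulus covariance near-singular and STRF recovery ill-posed — the same
  reason receptive-field mapping experiments use rich fast modulations
  (ripples, TORCs).  An optional contrast envelope alternates low/high
  contrast blocks with abrupt switches, the classic regime for exposing
  gain-control dynamics.
* **Neurons** — Gabor-like random STRFs (unit Frobenius norm), double
  exponential outputs with `k < 0` (rate increases with drive), baseline
  near 0.05, saturation near 1.
* **Adaptation** — `gain_control`: multiplicative gain with
  `dg/dt = [(1−g) − γ·g·drive]/τ` (drive normalized to mean 1, so the
  equilibrium gain under constant drive d is `1/(1+γd)` and relaxation
  takes O(τ) bins); `long_memory`: an additive slow component, the
  stimulus energy convolved with an exponential kernel of time constant τ
  (support 4τ), scaled to γ times the rate's standard deviation.
* **Noise** — Gaussian on the rate (default) or Poisson on the expected
  count per bin; optional slow per-trial drift for detrending tests.
  `noise_sigma_for_ceiling` inverts the closed-form relation between noise
  level and the expected PSTH correlation of a perfect model, to simulate
  at a chosen noise ceiling.

What passing tests on these data do **not** show: real recordings have
non-Gaussian noise, non-stationarities, correlated trial-to-trial
variability and far richer nonlinearities; results here validate the
machinery (gradients, protocol, metrics, truncation logic), not biological
conclusions.

A note on the two adaptive mechanisms: the additive long-memory component
is a linear functional of the stimulus history, so a randomly initialized
recurrent state plus a trained readout can capture it without any temporal
credit assignment (reservoir-style).  It is therefore used where *memory*
is the point (dream-length curves, carried-state tests).  The multiplicative
gain-control mechanism requires learned state dynamics, and is used where
*learning through time* is the point (the truncation-ordering experiment).

## Problem sizes and optimization settings in the built-in experiments

The experiment suite (tests and `scripts/acceptance.py`) simulates at desk
scale: 6–20 neurons, 8–40 clips of 200–500 bins, 10 trials.  Learning
rates are chosen per experiment family (1e-3 for linear fits following the
standard protocol; 1e-2 to 2e-2 for the small recurrent models, which
otherwise converge far more slowly than their stateless counterparts at
these sizes), with batch sizes of 1 clip for stateless and 4 clips for
recurrent fits, and epoch caps in the low hundreds.  These are convergence
choices, not claims; the compared models within any experiment always share
the data, splits and seeds.

## Known limitations

* The Transformer recomputes attention over its window at every output bin
  (`O(T·W²)`); fine at these scales, wasteful for long sequences.
* The SSM core is real-diagonal; oscillatory kernels (complex poles) are
  out of scope.
* Single recurrent layer only; deeper stateful stacks are not implemented.
* Converters for the public electrophysiology archives are documented
  stubs — the archives require credentialed multi-GB downloads.
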