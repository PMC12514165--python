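# strfnet

Encoding models of auditory neural responses: from classical
spectro-temporal receptive fields (STRFs) to stateful recurrent networks,
with a gradient-based toolkit for reverse-engineering what any fitted model
listens for.

## The problem

Auditory neurons are usually modelled as a causal map from a stimulus
cochleagram `x ∈ R^{F×T}` (F frequency bands, T time bins) to firing rates
`r̂ ∈ R^{N×T}`.  Classical models convolve the cochleagram with a finite
spectro-temporal window — so their memory ends abruptly at the window edge,
even though real neurons adapt over seconds (gain control, stimulus-specific
adaptation, synaptic depression).  This package implements both families
under one contract:

* **Stateless**: linear STRF (`linear`), linear–nonlinear (`ln`), a hidden
  filter bank with sigmoid units (`nrf`), a 2-D CNN (`cnn2d`), and a
  windowed Transformer (`transformer`).
* **Stateful**: `dnet` (leaky-integrator hidden units, 5-bin input window)
  and the StateNet family (`statenet`): a tonotopic locally connected
  downsampling layer → batch norm → one recurrent core
  (Elman / GRU / LSTM / diagonal state-space model) → linear per-neuron
  readout, consuming a single time bin per step.

All nonlinear models share the double-exponential output nonlinearity

    f(x) = a · exp(−exp(k·x − s)) + b

with per-neuron learnable `(a, b, k, s)`.  Fitting minimizes the MSE between
predicted rates and the trial-averaged PSTH (Adam, constant learning rate,
clip-level 70–10–20 splits, early stopping on validation loss).  Accuracy is
reported as the raw Pearson correlation `CC_raw` and the noise-corrected

    CC_norm = Cov(r, r̂) / sqrt(SP · Var(r̂)),
    SP = [Var(Σ_m r^(m)) − Σ_m Var(r^(m))] / (M(M−1)),

whose attainable ceiling is 1 regardless of trial-to-trial noise.

Stateful models can be trained with truncated backpropagation through time,
TBPTT(K1=1, K2=K), with or without a gradient-free warmup of the hidden
state, to probe how much temporal credit assignment the fit really needs.

For interpretation, the gradient of a response-maximization loss with
respect to the input ("GradMap") generalizes the STRF to any differentiable
model, and iterating the ascent produces optimal stimuli ("Dreams"); energy
traces, cross-model similarity matrices and dream-length activation curves
quantify each model's effective memory.

Everything runs on numpy with reverse-mode automatic differentiation
(`autograd`); no GPU is required.  A built-in simulator generates
ground-truth linear–nonlinear populations with optional gain-control or
long-memory adaptation, multi-trial noise and slow drift, so every claim is
testable against known truth.

## Worked example

```python
import strfnet as sn
from strfnet import synthetic

stimuli = synthetic.generate_stimuli(F=16, T=400, n_clips=10, seed=0)
truth = synthetic.random_ground_truth(6, F=16, W=10, noise_sigma=0.2, seed=0)
dataset = synthetic.simulate_neurons(stimuli, truth, M=10)

results = sn.NeuralEncoding(dataset, architecture="ln", trf_bins=10).fit(
    seeds=[0], batch_size=1, max_epochs=150)
print(results.summary())
```

prints

```
Neural encoding model fit
============================================================
architecture:     ln
neurons (N):      6
freq bands (F):   16
temporal window:  10 bins
parameters:       990
seeds:            [0]
epochs (best):    [149]
------------------------------------------------------------
       cc_raw  cc_norm
split
train  0.8484   0.9234
valid  0.8199   0.8965
test   0.8409   0.9261
------------------------------------------------------------
CC_norm is noise-corrected (attainable ceiling 1).
```

Test `CC_norm ≈ 0.93` against a `CC_raw ≈ 0.84`: the correction removes the
part of the error that no model could explain given only 10 noisy trials.
The fitted model can then be reverse-engineered:

```python
g = results.gradmap(neuron=0, T=50)       # F x 50 GradMap
d = results.dream(neuron=0, T=50)         # optimized stimulus + loss curve
```

A command-line interface mirrors the library (`strfnet simulate / fit /
eval / dream / similarity`); see `strfnet --help`.

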