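"""Gradient-based reverse engineering of trained encoders.

A *GradMap* generalizes the linear STRF to any differentiable model: it is
the gradient of a response-maximization loss with respect to the input
spectrogram, evaluated at an uninformative probe (the all-zero "null"
stimulus).  The loss is the negative mean predicted activity of a target
neuron set at the final bin, ``L = -(1/|targets|) * sum_n r_hat_n[T]``, so
the map answers "in which direction should the stimulus move to excite the
target most?" — the gradient-based analogue of the spike-triggered average.

Iterating gradient-ascent updates of the stimulus itself (with an Adam-style
optimizer) produces a *Dream*: an optimized spectrogram that maximally
drives the target.  The per-latency mean of squared GradMap entries is the
map's *energy* — a trace of how far back in time the model integrates
evidence.  Cross-model functional similarity is the Pearson correlation of
flattened GradMaps, averaged across neurons.

For stateful models the gradients are computed by full unrolling over the
probe length, regardless of how the model was trained.  Batch-normalization
layers always use their frozen statistics here, so every map is a property
of the frozen model.

Latency convention: latency 0 is the loss bin (time T); latency ``tau``
refers to bin ``T - tau``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd
import autograd.numpy as anp
import numpy as np
import pandas as pd

from .nets.encoder import CausalEncoder

DEFAULT_DREAM_ITERS = 1500
DREAM_CONVERGENCE_WINDOW = 50
DREAM_CONVERGENCE_RTOL = 1e-4


@dataclass
class GradMap:
    """F x T input-gradient map for (model, target set, horizon T)."""

    values: np.ndarray
    target: tuple[int, ...]
    model_id: str = ""
    iteration_index: int = 0

    @property
    def horizon(self) -> int:
        return self.values.shape[1]


@dataclass
class Dream:
    """An iteratively optimized stimulus and its loss trajectory."""

    values: np.ndarray
    loss_trajectory: np.ndarray
    target: tuple[int, ...]
    lr: float
    betas: tuple[float, float]
    gradmaps: list[GradMap] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.loss_trajectory)


@dataclass
class EnergyTrace:
    """Mean squared GradMap amplitude per latency (index 0 = loss bin)."""

    values: np.ndarray
    normalized: bool


def _as_targets(target) -> tuple[int, ...]:
    targets = (target,) if np.isscalar(target) else tuple(target)
    if len(targets) == 0:
        raise ValueError("target set must be non-empty")
    return targets


def _loss_fn(model: CausalEncoder, targets: tuple[int, ...]):
    tset = np.array(sorted(set(targets)))

    def loss(x):
        pred = model.forward(x)
        return -anp.mean(pred[tset, -1])

    return loss


def gradmap(model: CausalEncoder, target, T: int,
            probe: np.ndarray | None = None) -> GradMap:
    """Gradient of the response-maximization loss at the probe stimulus.

    ``probe`` defaults to the null (all-zero) F x T spectrogram.  Duplicated
    targets are collapsed (the loss is a mean over the unique target set).
    """
    targets = _as_targets(target)
    if T < 1:
        raise ValueError("T must be >= 1")
    if probe is None:
        probe = np.zeros((model.spec.n_freqs, T))
    g = autograd.grad(_loss_fn(model, targets))(np.asarray(probe, dtype=float))
    return GradMap(values=np.asarray(g), target=targets)


def dream(model: CausalEncoder, target, T: int,
          n_iters: int = DEFAULT_DREAM_ITERS, lr: float = 1e-2,
          betas: tuple[float, float] = (0.9, 0.999),
          keep_gradmaps: bool = False,
          until_convergence: bool = False,
          optimizer: str = "adam",
          clip_min: float | None = None) -> Dream:
    """Gradient-ascent optimization of the stimulus from the null probe.

    Runs ``n_iters`` updates ``x <- x - update(g)`` (the loss is the
    negative target activity, so this ascends the response) with Adam
    (default) or plain gradient descent (``optimizer="sgd"``, update
    ``lr * g``).  With ``until_convergence`` the iteration stops early once
    the relative loss change over the last 50 iterations falls below 1e-4.
    ``clip_min`` projects the stimulus onto ``x >= clip_min`` after each
    update (cochleagrams are non-negative; unconstrained ascent can drive
    gated recurrent models into saturation with out-of-range inputs).
    """
    if optimizer not in ("adam", "sgd"):
        raise ValueError(f"unknown optimizer {optimizer!r}")
    targets = _as_targets(target)
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    loss = _loss_fn(model, targets)
    vag = autograd.value_and_grad(loss)
    x = np.zeros((model.spec.n_freqs, T))
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2 = betas
    losses = []
    maps = []
    for i in range(n_iters):
        val, g = vag(x)
        losses.append(float(val))
        if keep_gradmaps:
            maps.append(GradMap(values=np.asarray(g), target=targets,
                                iteration_index=i))
        if optimizer == "sgd":
            x = x - lr * g
        else:
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** (i + 1))
            vhat = v / (1 - b2 ** (i + 1))
            x = x - lr * mhat / (np.sqrt(vhat) + 1e-8)
        if clip_min is not None:
            x = np.maximum(x, clip_min)
        if until_convergence and i >= DREAM_CONVERGENCE_WINDOW:
            prev = losses[i - DREAM_CONVERGENCE_WINDOW]
            if abs(prev - losses[i]) < DREAM_CONVERGENCE_RTOL * max(abs(prev), 1e-12):
                break
    return Dream(values=x, loss_trajectory=np.array(losses), target=targets,
                 lr=lr, betas=betas, gradmaps=maps)


def gradmap_energy(g: GradMap | np.ndarray, normalize: bool = False) -> EnergyTrace:
    """Per-latency energy ``E[t] = (1/F) * sum_f g[f, t]**2``.

    The returned trace is indexed by latency: entry 0 is the loss bin,
    entry ``tau`` is ``tau`` bins in the past.  With ``normalize`` the trace
    is divided by its maximum (an all-zero map is returned as zeros, with a
    warning).
    """
    values = g.values if isinstance(g, GradMap) else np.asarray(g)
    energy = np.mean(values ** 2, axis=0)[::-1].copy()
    if normalize:
        peak = energy.max()
        if peak <= 0:
            warnings.warn("all-zero GradMap cannot be normalized; returning zeros")
        else:
            energy = energy / peak
    return EnergyTrace(values=energy, normalized=normalize)


def similarity_matrix(gradmaps: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise functional similarity of models from their GradMaps.

    ``gradmaps`` maps a model identifier to an ``(N, F, T)`` array of maps
    (one per neuron, shared neuron order and F x T shape across models).
    For each model pair and neuron both maps are flattened and compared with
    Pearson correlation; coefficients are averaged across neurons.  The
    result is symmetric with unit diagonal.  For several datasets, average
    the per-dataset matrices.
    """
    names = list(gradmaps)
    arrays = {}
    shape = None
    for name in names:
        a = np.asarray(gradmaps[name], dtype=float)
        if a.ndim == 2:
            a = a[None]
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError("all models must provide maps of identical shape")
        arrays[name] = a.reshape(a.shape[0], -1)
    n_models = len(names)
    sim = np.eye(n_models)
    for i in range(n_models):
        for j in range(i + 1, n_models):
            ccs = []
            for a, b in zip(arrays[names[i]], arrays[names[j]]):
                sa, sb = a.std(), b.std()
                ccs.append(0.0 if sa <= 0 or sb <= 0 else
                           float(np.corrcoef(a, b)[0, 1]))
            sim[i, j] = sim[j, i] = float(np.mean(ccs))
    return pd.DataFrame(sim, index=names, columns=names)


def dream_length_curve(model: CausalEncoder, targets, max_len: int = 200,
                       lengths=None, n_iters: int = DEFAULT_DREAM_ITERS,
                       lr: float = 1e-2,
                       clip_min: float | None = 0.0) -> pd.Series:
    """Mean target activation of converged Dreams as a function of length.

    For each length ``l`` a Dream of ``l`` bins is optimized until loss
    convergence (capped at ``n_iters``); the optimized stimulus is fed to
    the model and the predicted activity of each target at the final bin is
    recorded and averaged over targets.  The curve is normalized by its
    maximum.  ``lengths`` may restrict the evaluated lengths (default:
    every length 1..max_len).  Dreams are constrained to the non-negative
    cochleagram range by default (``clip_min=0``) so that the probe stays in
    the stimulus domain the model was fitted on.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    targets = _as_targets(targets)
    lengths = list(range(1, max_len + 1)) if lengths is None else sorted(lengths)
    activations = []
    for length in lengths:
        d = dream(model, targets, T=length, n_iters=n_iters, lr=lr,
                  until_convergence=True, clip_min=clip_min)
        pred = np.asarray(model.forward(d.values))
        activations.append(float(np.mean(pred[list(set(targets)), -1])))
    curve = np.array(activations)
    if curve.max() > 0:
        curve = curve / curve.max()
    else:
        warnings.warn("non-positive activation curve left unnormalized")
    return pd.Series(curve, index=pd.Index(lengths, name="dream_length"),
                     name="normalized_activation")
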