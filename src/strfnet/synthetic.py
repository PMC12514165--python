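"""Ground-truth stimulus/response simulators.

These stand in for electrophysiology recordings when testing and benchmarking
the encoding models.  Stimuli are smooth Gaussian random fields passed through
a softplus, emulating the spectro-temporal smoothness and non-negativity of
log-compressed cochleagrams of natural sounds.  Neurons follow a
linear-nonlinear (LN) cascade — a causal spectro-temporal receptive field
(STRF) followed by a double-exponential output nonlinearity — optionally
extended with one of two adaptive mechanisms:

``gain_control``
    A multiplicative gain ``g[t]`` with first-order recovery and drive-
    dependent depression, ``dg/dt = (1 - g)/tau - gamma * g * drive[t]``:
    a minimal contrast-gain-control / synaptic-depression mechanism.

``long_memory``
    An additive slow component obtained by convolving the stimulus energy
    with an exponential kernel of time constant ``tau`` (support ``4 * tau``
    bins), creating dependence on the distant past that no finite-window
    model can capture.

Observation noise is Gaussian on the rate (default) or Poisson on the
expected count per bin.  The ground truth (STRFs, output parameters,
noise-free rates) is kept alongside the generated dataset so recovery tests
can compare estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import Clip, Cochleagram, EncodingDataset, NeuronRecord, compute_psth


def generate_stimuli(
    F: int = 16,
    T: int = 500,
    n_clips: int = 10,
    smoothness: tuple[float, float] = (0.7, 0.7),
    seed: int = 0,
    dt: float = 0.005,
    contrast_envelope_scale: float | None = None,
) -> list[Cochleagram]:
    """Generate smooth, non-negative synthetic cochleagrams.

    White Gaussian noise is low-pass filtered along frequency and time with
    Gaussian kernels of scale ``smoothness = (freq_scale, time_scale)`` (in
    bins), standardized, and passed through a softplus.  The result has the
    two key statistics of natural cochleagrams that matter for STRF
    estimation: correlations decaying with frequency and time separation, and
    strictly non-negative values.

    ``contrast_envelope_scale``, if given, multiplies each clip by a slow
    positive envelope (Gaussian-filtered noise with that time scale, in bins)
    so that stimulus contrast fluctuates slowly — the regime in which
    gain-control dynamics matter.
    """
    if F < 1 or T < 1 or n_clips < 1:
        raise ValueError("F, T and n_clips must be >= 1")
    freq_scale, time_scale = smoothness
    if freq_scale <= 0 or time_scale <= 0:
        raise ValueError("smoothness scales must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.logspace(np.log10(500.0), np.log10(16000.0), F)
    clips = []
    for i in range(n_clips):
        z = rng.standard_normal((F, T))
        z = ndimage.gaussian_filter(z, sigma=(freq_scale, time_scale),
                                    mode="wrap")
        z = (z - z.mean()) / z.std()
        if contrast_envelope_scale is not None:
            # alternating low/high-contrast blocks with abrupt switches, as
            # in classic contrast gain-control protocols: the gain state
            # after a switch depends on elapsed time, not on the local window
            block = max(int(contrast_envelope_scale), 1)
            n_blocks = -(-T // block)
            hi_first = bool(rng.integers(2))
            env = np.empty(T)
            for bi in range(n_blocks):
                hi = (bi % 2 == 0) == hi_first
                env[bi * block:(bi + 1) * block] = 1.7 if hi else 0.3
            z = z * env[None, :]
        values = np.log1p(np.exp(z))  # softplus
        clips.append(Cochleagram(values=values, freqs=freqs, dt=dt,
                                 clip_id=f"clip{i:03d}"))
    return clips


@dataclass
class SyntheticGroundTruth:
    """The generative parameters of a simulated population.

    ``strfs[n]`` is the F x W receptive field of neuron ``n`` (lag axis
    ordered oldest-to-newest, so column ``W-1`` acts on the current bin).
    ``output_params[n]`` is the (a, b, k, s) quadruple of the
    double-exponential output nonlinearity ``f(x) = a*exp(-exp(k*x - s)) + b``.
    """

    strfs: np.ndarray                      # (N, F, W)
    output_params: np.ndarray              # (N, 4) rows (a, b, k, s)
    adaptation: str = "none"               # none | gain_control | long_memory
    tau: float = 100.0                     # adaptation time constant, bins
    gamma: float = 0.0                     # adaptation strength in [0, 1]
    noise_model: str = "gaussian"          # gaussian | poisson
    noise_sigma: float = 0.1
    seed: int = 0
    # filled by simulate_neurons: noise-free rate per clip, (N, T) each
    rates: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.adaptation not in ("none", "gain_control", "long_memory"):
            raise ValueError(f"unknown adaptation {self.adaptation!r}")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")

    @property
    def n_neurons(self) -> int:
        return self.strfs.shape[0]


def random_ground_truth(
    n_neurons: int,
    F: int = 16,
    W: int = 10,
    adaptation: str = "none",
    tau: float = 100.0,
    gamma: float = 0.0,
    noise_model: str = "gaussian",
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Draw a population of smooth random STRFs with gentle output nonlinearity.

    Each STRF is a localized excitatory/inhibitory Gabor-like patch (smoothed
    difference of two Gaussian bumps) normalized to unit Frobenius norm.  The
    output nonlinearity uses ``k < 0`` so that rate increases with filter
    drive, a baseline ``b`` near 0.05 and saturation ``a`` near 1.
    """
    rng = np.random.default_rng(seed)
    strfs = np.empty((n_neurons, F, W))
    ff, tt = np.meshgrid(np.arange(F), np.arange(W), indexing="ij")
    for n in range(n_neurons):
        f0 = rng.uniform(0.2 * F, 0.8 * F)
        t0 = rng.uniform(0.4 * W, 0.9 * W)
        sf = rng.uniform(0.08 * F, 0.2 * F)
        st = rng.uniform(0.15 * W, 0.3 * W)
        bump = np.exp(-0.5 * (((ff - f0) / sf) ** 2 + ((tt - t0) / st) ** 2))
        f1 = f0 + rng.choice([-1, 1]) * rng.uniform(0.15 * F, 0.3 * F)
        side = np.exp(-0.5 * (((ff - f1) / sf) ** 2 + ((tt - t0) / st) ** 2))
        strf = bump - 0.7 * side
        strf = strf / np.linalg.norm(strf)
        strfs[n] = strf
    a = rng.uniform(0.8, 1.2, n_neurons)
    b = rng.uniform(0.0, 0.1, n_neurons)
    k = -rng.uniform(0.8, 1.2, n_neurons)
    s = rng.uniform(-0.2, 0.2, n_neurons)
    return SyntheticGroundTruth(
        strfs=strfs, output_params=np.column_stack([a, b, k, s]),
        adaptation=adaptation, tau=tau, gamma=gamma,
        noise_model=noise_model, noise_sigma=noise_sigma, seed=seed)


def _double_exponential(x: np.ndarray, a, b, k, s) -> np.ndarray:
    inner = np.clip(k * x - s, -30.0, 30.0)
    return a * np.exp(-np.exp(inner)) + b


def _causal_drive(strf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Causal STRF convolution: drive[t] = sum_{f,j} strf[f,j] x[f, t-W+1+j]."""
    F, W = strf.shape
    T = x.shape[1]
    xp = np.concatenate([np.zeros((F, W - 1)), x], axis=1)
    idx = np.arange(T)[:, None] + np.arange(W)[None, :]
    return np.einsum("fw,ftw->t", strf, xp[:, idx])


def _gain_trajectory(drive: np.ndarray, tau: float, gamma: float) -> np.ndarray:
    """Integrate dg/dt = [(1 - g) - gamma * g * drive] / tau, g[0-] = 1.

    First-order recovery toward 1 and drive-dependent depression, both on
    the time scale ``tau`` (bins), so the equilibrium gain under constant
    drive d is 1 / (1 + gamma * d) and relaxation after a contrast switch
    takes O(tau) bins.  ``drive`` is non-negative with mean ~1, making
    ``gamma`` a dimensionless depression strength.
    """
    T = drive.shape[0]
    g = np.empty(T)
    prev = 1.0
    for t in range(T):
        prev = prev + ((1.0 - prev) - gamma * prev * drive[t]) / tau
        prev = min(max(prev, 0.0), 1.5)
        g[t] = prev
    return g


def noise_free_rates(
    stimuli: list[Cochleagram], truth: SyntheticGroundTruth
) -> list[np.ndarray]:
    """Noise-free population rate (N x T) for each stimulus clip."""
    rates = []
    for coch in stimuli:
        x = coch.values
        T = x.shape[1]
        pop = np.empty((truth.n_neurons, T))
        for n in range(truth.n_neurons):
            a, b, k, s = truth.output_params[n]
            drive = _causal_drive(truth.strfs[n], x)
            rate = _double_exponential(drive, a, b, k, s)
            if truth.adaptation == "gain_control":
                pos = np.maximum(drive, 0.0)
                pos = pos / max(pos.mean(), 1e-12)
                rate = rate * _gain_trajectory(pos, truth.tau, truth.gamma)
            elif truth.adaptation == "long_memory":
                L = int(4 * truth.tau)
                kern = np.exp(-np.arange(L) / truth.tau)
                kern /= kern.sum()
                energy = x.mean(axis=0)
                energy = energy - energy.mean()
                xp = np.concatenate([np.zeros(L - 1), energy])
                slow = np.convolve(xp, kern[::-1], mode="valid")
                rate = rate + truth.gamma * rate.std() / max(slow.std(), 1e-12) * slow
            pop[n] = rate
        rates.append(pop)
    return rates


def simulate_neurons(
    stimuli: list[Cochleagram],
    truth: SyntheticGroundTruth,
    M: int = 10,
    smooth_window_bins: int = 1,
    drift_sigma: float = 0.0,
) -> EncodingDataset:
    """Simulate an M-trial population recording for the given stimuli.

    Trials are independent noise realizations around the noise-free rate
    (Gaussian on the rate, or Poisson on the expected count per bin, per
    ``truth.noise_model``).  ``drift_sigma`` adds an independent slow random
    drift per trial (Gaussian-filtered noise, scale 200 bins), for exercising
    detrending.  PSTHs are the trial means, smoothed with
    ``smooth_window_bins`` (odd; 1 = none).  The noise-free rates are stored
    into ``truth.rates``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    W = truth.strfs.shape[2]
    if any(c.n_bins < W for c in stimuli):
        raise ValueError("STRF width W exceeds a clip length T")
    rng = np.random.default_rng(truth.seed)
    rates = noise_free_rates(stimuli, truth)
    truth.rates = rates
    neurons = [f"n{n:03d}" for n in range(truth.n_neurons)]
    clips = []
    for coch, pop in zip(stimuli, rates):
        T = pop.shape[1]
        responses = {}
        for n, nid in enumerate(neurons):
            rate = pop[n]
            if truth.noise_model == "gaussian":
                trials = rate[None, :] + truth.noise_sigma * rng.standard_normal((M, T))
            else:
                lam = np.maximum(rate, 0.0) * coch.dt
                trials = rng.poisson(lam[None, :], size=(M, T)) / coch.dt
            if drift_sigma > 0:
                drift = ndimage.gaussian_filter1d(
                    rng.standard_normal((M, T)), sigma=200.0, axis=1,
                    mode="reflect")
                drift = drift / np.maximum(drift.std(axis=1, keepdims=True), 1e-12)
                trials = trials + drift_sigma * drift
            psth = compute_psth(trials, smooth_window_bins)
            responses[nid] = NeuronRecord(trials=trials, psth=psth)
        clips.append(Clip(cochleagram=coch, responses=responses))
    return EncodingDataset(clips=clips, neurons=neurons, population_mode=True)


def noise_sigma_for_ceiling(
    rates: list[np.ndarray], M: int, ceiling: float
) -> float:
    """Gaussian noise level giving a target noise ceiling for the true rate.

    With additive i.i.d. Gaussian noise of variance ``sigma**2`` on each of
    ``M`` trials, the expected Pearson correlation between the true rate and
    the M-trial PSTH is ``1 / sqrt(1 + sigma**2 / (M * Var(rate)))``.
    Inverting for ``sigma`` gives the noise level at which even a perfect
    model scores ``ceiling`` in raw correlation — the regime the noise-
    corrected metric is designed for.
    """
    if not 0 < ceiling < 1:
        raise ValueError("ceiling must be in (0, 1)")
    var = float(np.mean([np.var(pop, axis=1).mean() for pop in rates]))
    return float(np.sqrt(M * var * (1.0 / ceiling**2 - 1.0)))
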