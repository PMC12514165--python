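"""Stimulus/response containers and preprocessing for auditory encoding models.

The universal stimulus representation is the cochleagram: an ``F x T``
non-negative matrix of compressed spectral power, with an ascending frequency
axis (Hz) and a fixed time-bin duration (seconds).  Neural responses are
multi-trial matrices (``M x T``) aligned bin-for-bin with the stimulus; the
regression target is the PSTH (trial average, optionally smoothed with a
Hanning window).  Intracellular traces can additionally be detrended with a
running-median + Gaussian ("MedGauss") filter to remove slow recording drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass
class Cochleagram:
    """An ``F x T`` spectrogram-like stimulus matrix.

    Parameters
    ----------
    values : ndarray, shape (F, T)
        Compressed spectral power, finite, arbitrary units.
    freqs : ndarray, shape (F,)
        Strictly increasing centre frequencies in Hz.
    dt : float
        Time-bin duration in seconds.
    clip_id : str
        Identifier of the stimulus clip.
    """

    values: np.ndarray
    freqs: np.ndarray
    dt: float
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cochleagram values must be 2-D (F x T)")
        F, T = self.values.shape
        if F < 1 or T < 1:
            raise ValueError("cochleagram must have F >= 1 and T >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cochleagram values must be finite")
        if self.freqs.shape != (F,):
            raise ValueError("freqs must have length F")
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs <= 0):
            raise ValueError("freqs must be strictly increasing and positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_freqs(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class NeuronRecord:
    """Multi-trial responses of one neuron to one clip.

    ``psth`` is the trial mean after any configured smoothing and is stored
    explicitly so that downstream code never recomputes it with different
    conventions.
    """

    trials: np.ndarray           # (M, T)
    psth: np.ndarray             # (T,)
    modality: str = "spikes"     # "spikes" | "membrane_potential"

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        self.psth = np.asarray(self.psth, dtype=float)
        if self.trials.shape[1] != self.psth.shape[0]:
            raise ValueError("trials and psth must share T")
        if self.modality not in ("spikes", "membrane_potential"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


@dataclass
class Clip:
    """One stimulus clip with the responses recorded for it."""

    cochleagram: Cochleagram
    responses: dict[str, NeuronRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = self.cochleagram.n_bins
        for nid, rec in self.responses.items():
            if rec.psth.shape[0] != T:
                raise ValueError(
                    f"response of neuron {nid!r} has T={rec.psth.shape[0]}, "
                    f"stimulus has T={T}"
                )


@dataclass
class EncodingDataset:
    """A collection of clips with per-neuron responses.

    ``population_mode`` is true iff every clip carries a response for every
    neuron, in which case one shared model can predict the whole population.
    ``split_labels`` (if set) assigns each clip to one of
    ``{"train", "valid", "test"}``.
    """

    clips: list[Clip]
    neurons: list[str]
    population_mode: bool = True
    split_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.population_mode:
            for clip in self.clips:
                missing = [n for n in self.neurons if n not in clip.responses]
                if missing:
                    raise ValueError(
                        f"population_mode dataset: clip "
                        f"{clip.cochleagram.clip_id!r} lacks responses for "
                        f"{missing}"
                    )
        if self.split_labels is not None:
            if len(self.split_labels) != len(self.clips):
                raise ValueError("split_labels must have one entry per clip")
            bad = set(self.split_labels) - {"train", "valid", "test"}
            if bad:
                raise ValueError(f"unknown split labels {bad}")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_freqs(self) -> int:
        return self.clips[0].cochleagram.n_freqs

    def clips_in(self, split: str) -> list[Clip]:
        if self.split_labels is None:
            raise ValueError("dataset has no split labels; call split_dataset")
        return [c for c, s in zip(self.clips, self.split_labels) if s == split]


def hanning_smooth(series: np.ndarray, window_bins: int) -> np.ndarray:
    """Smooth a 1-D series with a unit-sum Hanning kernel.

    ``window_bins`` must be odd; 1 (or 3, whose Hanning window is a unit
    impulse) is the identity.  Edges are handled by reflection so a constant
    series stays constant.
    """
    series = np.asarray(series, dtype=float)
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 1")
    if window_bins == 1:
        return series.copy()
    kernel = np.hanning(window_bins)
    kernel = kernel / kernel.sum()
    half = window_bins // 2
    padded = np.pad(series, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def compute_psth(trials: np.ndarray, smooth_window_bins: int = 1) -> np.ndarray:
    """Trial-average response, optionally Hanning-smoothed.

    The PSTH is the mean over the M trials; smoothing (when requested) is
    applied to the average.  Averaging and linear smoothing commute, so the
    order does not matter numerically.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.size == 0:
        raise ValueError("trials must be non-empty")
    mean = trials.mean(axis=0)
    return hanning_smooth(mean, smooth_window_bins)


def detrend_medgauss(
    trace: np.ndarray,
    median_width_bins: int = 201,
    gauss_sigma_bins: float = 50.0,
) -> np.ndarray:
    """Remove slow drift from a trace with a median-then-Gaussian filter.

    A running median (width ``median_width_bins``) tracks the slow trend while
    ignoring fast transients; Gaussian smoothing (``gauss_sigma_bins``) removes
    the staircase artifacts of the median.  The smoothed trend is subtracted.
    Intended for intracellular membrane-potential traces, whose baseline can
    drift with electrode motion; supra-threshold signals (PSTHs) do not need
    it.
    """
    trace = np.asarray(trace, dtype=float)
    T = trace.shape[0]
    if median_width_bins <= 0 or gauss_sigma_bins <= 0:
        raise ValueError("filter widths must be positive")
    if median_width_bins >= T:
        raise ValueError("median width must be smaller than the trace length")
    trend = ndimage.median_filter(trace, size=median_width_bins, mode="reflect")
    trend = ndimage.gaussian_filter1d(trend, sigma=gauss_sigma_bins, mode="reflect")
    return trace - trend


def split_dataset(
    dataset: EncodingDataset,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> EncodingDataset:
    """Partition clips into train/valid/test subsets.

    Whole clips are assigned to subsets (never bins within a clip) to avoid
    temporal leakage.  Counts are the rounded ratios, adjusted so that every
    subset is non-empty; the assignment is a seeded permutation and is
    deterministic per (dataset size, ratios, seed).
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive numbers")
    if abs(sum(ratios) - 1.0) > 1e-8:
        raise ValueError("ratios must sum to 1")
    n = len(dataset.clips)
    if n < 3:
        raise ValueError("need at least 3 clips to build three subsets")

    n_train = int(round(ratios[0] * n))
    n_valid = int(round(ratios[1] * n))
    n_train = max(1, n_train)
    n_valid = max(1, n_valid)
    n_test = n - n_train - n_valid
    while n_test < 1:  # steal from the largest subset
        if n_train >= n_valid:
            n_train -= 1
        else:
            n_valid -= 1
        n_test = n - n_train - n_valid

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:n_train + n_valid]] = "valid"
    labels[order[n_train + n_valid:]] = "test"
    return replace(dataset, split_labels=list(labels))
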