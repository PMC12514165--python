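"""Raw and noise-corrected correlation metrics.

A model that predicted the neuron's true underlying rate perfectly would
still score below 1 in raw Pearson correlation against a finite-trial PSTH,
because the PSTH contains trial-to-trial noise.  The normalized coefficient
``CC_norm`` replaces the PSTH variance in the denominator with an unbiased
estimate of the *signal power* SP — the variance of the repeatable part of
the response — so that the attainable ceiling is 1:

    CC_raw  = Cov(r, r_hat) / sqrt(Var(r) Var(r_hat))
    SP      = [Var(sum_m r_m) - sum_m Var(r_m)] / (M (M - 1))
    CC_norm = Cov(r, r_hat) / sqrt(SP * Var(r_hat))

with ``r`` the M-trial mean and all variances population variances
(divide-by-count) along time, which makes the identical-trials identity
``SP = Var(r)`` exact.  With a single trial, CC_norm is defined equal to
CC_raw (a conservative lower bound).  Degenerate cases (zero variance,
non-positive SP under heavy noise) return 0 with a warning rather than an
undefined value, keeping population averages well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - a.mean()) * (b - b.mean())))


def _degenerate(var: float, x: np.ndarray) -> bool:
    """Zero variance up to floating-point noise on a constant series."""
    return var <= 1e-15 * max(1.0, float(np.mean(x * x)))


def cc_raw(pred: np.ndarray, psth: np.ndarray) -> float:
    """Pearson correlation between a prediction and the PSTH along time."""
    pred = np.asarray(pred, dtype=float).ravel()
    psth = np.asarray(psth, dtype=float).ravel()
    if pred.shape != psth.shape:
        raise ValueError("pred and psth must have the same length")
    vp, vr = np.var(pred), np.var(psth)
    if _degenerate(vp, pred) or _degenerate(vr, psth):
        warnings.warn("degenerate (zero-variance) input to cc_raw; returning 0")
        return 0.0
    return _cov(psth, pred) / np.sqrt(vr * vp)


def signal_power(trials: np.ndarray) -> float:
    """Unbiased estimate of the trial-repeatable response variance.

    ``trials``: (M, T) with M >= 2.  Can be negative when the responses are
    dominated by noise; callers decide how to handle that (see cc_norm).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    M = trials.shape[0]
    if M < 2:
        raise ValueError("signal power needs at least 2 trials")
    total = np.var(trials.sum(axis=0))
    per_trial = np.var(trials, axis=1).sum()
    return float((total - per_trial) / (M * (M - 1)))


def cc_norm(pred: np.ndarray, trials: np.ndarray) -> float:
    """Noise-corrected correlation between a prediction and multi-trial data.

    With one trial, returns ``cc_raw`` (fully-repeatable convention).  If the
    signal-power estimate is non-positive the metric is undefined; returns 0
    with a warning.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[1] != pred.shape[0]:
        raise ValueError("pred and trials must share T")
    if trials.shape[0] == 1:
        return cc_raw(pred, trials[0])
    sp = signal_power(trials)
    vp = np.var(pred)
    if sp <= 0 or _degenerate(vp, pred):
        warnings.warn("non-positive signal power or constant prediction; "
                      "cc_norm set to 0")
        return 0.0
    r = trials.mean(axis=0)
    return _cov(r, pred) / np.sqrt(sp * vp)


@dataclass
class MetricReport:
    """Per-neuron metric bundle for one evaluation split."""

    cc_raw: float
    cc_norm: float
    signal_power: float
    n_trials: int
    n_bins: int


def report(pred: np.ndarray, trials: np.ndarray) -> MetricReport:
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    M, T = trials.shape
    sp = signal_power(trials) if M >= 2 else float(np.var(trials[0]))
    return MetricReport(
        cc_raw=cc_raw(pred, trials.mean(axis=0)),
        cc_norm=cc_norm(pred, trials),
        signal_power=sp, n_trials=M, n_bins=T)
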