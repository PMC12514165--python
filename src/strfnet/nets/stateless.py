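"""Stateless (finite temporal-window) encoder architectures.

* ``linear`` — per-neuron spectro-temporal receptive field (STRF) weights
  ``(N, F, W)`` plus bias; the classical linear STRF model.
* ``ln`` — linear followed by the per-unit double-exponential nonlinearity.
* ``nrf`` — a hidden bank of ``H`` spectro-temporal filters with batch
  normalization and a sigmoid, read out linearly into ``N`` units and passed
  through the double exponential (network receptive field model).
* ``cnn2d`` — stacked 2-D convolutions over (frequency, time) with BN +
  sigmoid, then a dense readout over (channel, frequency) features per time
  bin, and the double exponential.

All use left zero-padding in time so output length equals input length and
bin ``t`` depends only on bins ``<= t``.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .common import (batchnorm, default_nl_params, double_exponential,
                     sigmoid, time_windows, uniform_init)


# ---------------------------------------------------------------- linear / LN

def init_linear(rng, spec) -> dict:
    F, W, N = spec.n_freqs, spec.trf_bins, spec.n_neurons
    params = {
        "w": uniform_init(rng, (N, F, W), F * W),
        "b": uniform_init(rng, (N,), F * W),
    }
    if spec.use_bn:
        params["bn_gamma"] = np.ones(F)
        params["bn_beta"] = np.zeros(F)
    if spec.output_nl:
        params["nl"] = default_nl_params(N)
    return params


def forward_linear(params, x, spec, mode, stats, state=None):
    if spec.use_bn:
        x = batchnorm(x, params["bn_gamma"], params["bn_beta"], "bn_in",
                      mode, stats)
    wins = time_windows(x, spec.trf_bins)          # (B, F, T, W)
    y = anp.einsum("nfw,bftw->bnt", params["w"], wins) + params["b"][None, :, None]
    if spec.output_nl:
        y = double_exponential(y, params["nl"])
    return y, None


# ---------------------------------------------------------------- NRF

def init_nrf(rng, spec) -> dict:
    F, W, N, H = spec.n_freqs, spec.trf_bins, spec.n_neurons, spec.hidden
    params = {
        "wh": uniform_init(rng, (H, F, W), F * W),
        "bh": uniform_init(rng, (H,), F * W),
        "bn_gamma": np.ones(H),
        "bn_beta": np.zeros(H),
        "wr": uniform_init(rng, (N, H), H),
        "br": uniform_init(rng, (N,), H),
    }
    if spec.output_nl:
        params["nl"] = default_nl_params(N)
    return params


def forward_nrf(params, x, spec, mode, stats, state=None):
    wins = time_windows(x, spec.trf_bins)
    z = anp.einsum("hfw,bftw->bht", params["wh"], wins) + params["bh"][None, :, None]
    z = batchnorm(z, params["bn_gamma"], params["bn_beta"], "bn_h", mode, stats)
    h = sigmoid(z)
    y = anp.einsum("nh,bht->bnt", params["wr"], h) + params["br"][None, :, None]
    if spec.output_nl:
        y = double_exponential(y, params["nl"])
    return y, None


# ---------------------------------------------------------------- 2-D CNN

def _conv2d_causal(x, kernels, bias):
    """2-D convolution, 'same' in frequency, causal (left-padded) in time.

    ``x``: (B, C, F, T); ``kernels``: (C_out, C, kf, kt) with the time axis
    ordered oldest-to-newest.  Implemented as a sum of shifted views, which
    keeps the autograd graph small.
    """
    B, C, F, T = x.shape
    Co, _, kf, kt = kernels.shape
    pf_lo = (kf - 1) // 2
    pf_hi = kf - 1 - pf_lo
    xp = anp.concatenate(
        [anp.zeros((B, C, pf_lo, T)), x, anp.zeros((B, C, pf_hi, T))], axis=2)
    xp = anp.concatenate([anp.zeros((B, C, F + kf - 1, kt - 1)), xp], axis=3)
    out = 0.0
    for i in range(kf):
        for j in range(kt):
            out = out + anp.einsum(
                "oc,bcft->boft", kernels[:, :, i, j],
                xp[:, :, i:i + F, j:j + T])
    return out + bias[None, :, None, None]


def init_cnn2d(rng, spec) -> dict:
    F, N = spec.n_freqs, spec.n_neurons
    C = spec.cnn_channels
    kf, kt = spec.cnn_kernel
    params = {}
    c_in = 1
    for layer in range(spec.cnn_layers):
        fan = c_in * kf * kt
        params[f"conv{layer}_w"] = uniform_init(rng, (C, c_in, kf, kt), fan)
        params[f"conv{layer}_b"] = uniform_init(rng, (C,), fan)
        params[f"conv{layer}_gamma"] = np.ones(C)
        params[f"conv{layer}_beta"] = np.zeros(C)
        c_in = C
    params["wr"] = uniform_init(rng, (N, C, F), C * F)
    params["br"] = uniform_init(rng, (N,), C * F)
    if spec.output_nl:
        params["nl"] = default_nl_params(N)
    return params


def forward_cnn2d(params, x, spec, mode, stats, state=None):
    B, F, T = x.shape
    z = anp.reshape(x, (B, 1, F, T))
    for layer in range(spec.cnn_layers):
        z = _conv2d_causal(z, params[f"conv{layer}_w"], params[f"conv{layer}_b"])
        C = z.shape[1]
        flat = anp.reshape(z, (B, C, -1))
        flat = batchnorm(flat, params[f"conv{layer}_gamma"],
                         params[f"conv{layer}_beta"], f"bn{layer}", mode, stats)
        z = sigmoid(anp.reshape(flat, z.shape))
    y = anp.einsum("ncf,bcft->bnt", params["wr"], z) + params["br"][None, :, None]
    if spec.output_nl:
        y = double_exponential(y, params["nl"])
    return y, None


def cnn2d_window(spec) -> int:
    """Temporal receptive-field length of the stacked causal convolutions."""
    return 1 + spec.cnn_layers * (spec.cnn_kernel[1] - 1)
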