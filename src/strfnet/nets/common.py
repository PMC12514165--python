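"""Shared differentiable building blocks.

All forward computations are written against ``autograd.numpy`` so that both
parameter gradients (training) and input gradients (GradMaps/Dreams) come from
the same reverse-mode graph.  Parameters live in flat ``dict[str, ndarray]``
containers; forward functions are pure in (params, input).

Conventions
-----------
* Inputs are batched ``(B, F, T)``; outputs ``(B, N, T)``.
* Temporal windows are ordered oldest-to-newest: a weight tensor
  ``W[..., j]`` with ``j = 0 .. Wt-1`` acts on input bin ``t - Wt + 1 + j``,
  so the last lag column acts on the current bin.  The stimulus is left
  zero-padded, which preserves causality and output length.
* Batch normalization uses *frozen* running statistics in every
  differentiated pass; the statistics are refreshed from data between
  optimizer epochs (see ``training``).  The learnable scale/bias stay in the
  graph, so after training BN is a plain affine map that can be absorbed
  into neighbouring weights.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

BN_EPS = 1e-5
EXP_CLIP = 30.0


def double_exponential(x, params):
    """Per-unit output nonlinearity ``f(x) = a * exp(-exp(k*x - s)) + b``.

    ``b`` is the baseline rate, ``a`` the saturated rate, ``s`` the threshold
    and ``k`` the gain; none is sign-constrained, so the fit can recover
    either response orientation.  The inner exponent is clamped to ``+-30``
    to guard against overflow.

    Parameters
    ----------
    x : array, shape (..., N, T) or scalar-broadcastable
    params : array, shape (N, 4) with rows/columns (a, b, k, s), or (4,)
    """
    params = anp.atleast_2d(params)
    a, b, k, s = params[:, 0], params[:, 1], params[:, 2], params[:, 3]
    shape = (1,) * (anp.ndim(x) - 2) + (-1, 1) if anp.ndim(x) >= 2 else (-1,)
    a = anp.reshape(a, shape)
    b = anp.reshape(b, shape)
    k = anp.reshape(k, shape)
    s = anp.reshape(s, shape)
    inner = anp.clip(k * x - s, -EXP_CLIP, EXP_CLIP)
    return a * anp.exp(-anp.exp(inner)) + b


def sigmoid(z):
    return 1.0 / (1.0 + anp.exp(-anp.clip(z, -EXP_CLIP, EXP_CLIP)))


def time_windows(x, W: int):
    """Causal sliding windows along time.

    ``x``: (B, F, T) -> (B, F, T, W) where ``out[..., t, j] = x[..., t-W+1+j]``
    (zero for bins before the sequence start).
    """
    B, F, T = x.shape
    xp = anp.concatenate([anp.zeros((B, F, W - 1)), x], axis=2) if W > 1 else x
    idx = np.arange(T)[:, None] + np.arange(W)[None, :]
    return xp[:, :, idx]


def batchnorm(z, gamma, beta, key: str, mode: str, stats: dict):
    """Channel-wise batch normalization for (B, C, T) activations.

    mode ``"eval"`` uses the stored running statistics (identity stats if the
    layer has never been refreshed); mode ``"refresh"`` computes statistics
    from the current batch *and stores them* — it must only be called outside
    an autograd trace.
    """
    if mode == "refresh":
        zv = np.asarray(z)
        stats[key] = (zv.mean(axis=(0, 2)), zv.var(axis=(0, 2)))
    mean, var = stats.get(key, (0.0, 1.0))
    mean = anp.reshape(anp.asarray(mean), (1, -1, 1)) if np.ndim(mean) else mean
    var = anp.reshape(anp.asarray(var), (1, -1, 1)) if np.ndim(var) else var
    zn = (z - mean) / anp.sqrt(var + BN_EPS)
    return gamma[None, :, None] * zn + beta[None, :, None]


def layernorm(z, gamma, beta):
    """Normalize over the last axis (token embedding dimension)."""
    mean = anp.mean(z, axis=-1, keepdims=True)
    var = anp.var(z, axis=-1, keepdims=True)
    return gamma * (z - mean) / anp.sqrt(var + BN_EPS) + beta


# ---------------------------------------------------------------- LC layer

def lc_geometry(F: int, kernel: int, stride: int) -> tuple[int, int]:
    """Number of window positions H = ceil(F/stride) and total zero padding."""
    if kernel > F:
        raise ValueError("LC kernel cannot exceed the number of frequency bands")
    H = -(-F // stride)
    pad = max(0, (H - 1) * stride + kernel - F)
    return H, pad


def lc_apply(x, kernels, biases, stride: int):
    """Locally connected projection along frequency, vectorized over time.

    ``x``: (B, F, T); ``kernels``: (H, k) position-specific weights (no
    sharing across frequency, unlike a convolution); ``biases``: (H,).
    Frequency ends are zero-padded so that H = ceil(F/stride); window centres
    are ascending in frequency, preserving tonotopy.  Returns (B, H, T).
    """
    B, F, T = x.shape
    H, k = kernels.shape
    _, pad = lc_geometry(F, k, stride)
    lo = pad // 2
    hi = pad - lo
    if pad:
        xp = anp.concatenate(
            [anp.zeros((B, lo, T)), x, anp.zeros((B, hi, T))], axis=1)
    else:
        xp = x
    idx = (np.arange(H) * stride)[:, None] + np.arange(k)[None, :]
    wins = xp[:, idx]                      # (B, H, k, T)
    return anp.einsum("hk,bhkt->bht", kernels, wins) + biases[None, :, None]


def locally_connected_project(freq_vector, kernels, biases, stride: int):
    """LC projection of a single length-F spectral vector -> length-H."""
    out = lc_apply(anp.reshape(freq_vector, (1, -1, 1)), kernels, biases, stride)
    return out[0, :, 0]


# ---------------------------------------------------------------- init helpers

def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def default_nl_params(n: int) -> np.ndarray:
    """Initial (a, b, k, s) per unit: a gentle, increasing response curve."""
    return np.tile(np.array([1.0, 0.0, -1.0, 0.0]), (n, 1))
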