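"""Windowed Transformer encoder for neural response prediction.

To predict activity at bin ``t`` the model attends over the ``Wt`` most
recent stimulus bins (left zero-padded at the sequence start).  Each bin in
the window becomes one token: the frequency vector projected to an embedding
of size ``E``, plus a learned positional embedding indexed by position within
the window.  One encoder layer (multi-head self-attention + feed-forward,
post-layer-norm) transforms the tokens, which are then mean-pooled and read
out linearly into the ``N`` units, followed by the per-unit double
exponential.  Defaults: 1 layer, 4 heads, ``E = 48``.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .common import default_nl_params, double_exponential, layernorm, uniform_init


def init_transformer(rng, spec) -> dict:
    F, W, N, E = spec.n_freqs, spec.trf_bins, spec.n_neurons, spec.embed_dim
    if E % spec.n_heads:
        raise ValueError("embed_dim must be divisible by n_heads")
    ff = 4 * E
    params = {
        "proj_w": uniform_init(rng, (E, F), F),
        "proj_b": uniform_init(rng, (E,), F),
        "pos": 0.02 * rng.standard_normal((W, E)),
    }
    for layer in range(spec.n_layers):
        p = f"l{layer}_"
        params[p + "wq"] = uniform_init(rng, (E, E), E)
        params[p + "wk"] = uniform_init(rng, (E, E), E)
        params[p + "wv"] = uniform_init(rng, (E, E), E)
        params[p + "wo"] = uniform_init(rng, (E, E), E)
        params[p + "ln1_g"] = np.ones(E)
        params[p + "ln1_b"] = np.zeros(E)
        params[p + "ff1_w"] = uniform_init(rng, (ff, E), E)
        params[p + "ff1_b"] = uniform_init(rng, (ff,), E)
        params[p + "ff2_w"] = uniform_init(rng, (E, ff), ff)
        params[p + "ff2_b"] = uniform_init(rng, (E,), ff)
        params[p + "ln2_g"] = np.ones(E)
        params[p + "ln2_b"] = np.zeros(E)
    params["wr"] = uniform_init(rng, (N, E), E)
    params["br"] = uniform_init(rng, (N,), E)
    if spec.output_nl:
        params["nl"] = default_nl_params(N)
    return params


def _softmax(z):
    z = z - anp.max(z, axis=-1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=-1, keepdims=True)


def forward_transformer(params, x, spec, mode, stats, state=None):
    B, F, T = x.shape
    W, E, nh = spec.trf_bins, spec.embed_dim, spec.n_heads
    dh = E // nh
    # tokens of the left-padded stimulus, then sliding windows of W tokens
    xp = anp.concatenate([anp.zeros((B, F, W - 1)), x], axis=2)
    tok = anp.einsum("ef,bft->bte", params["proj_w"], xp) + params["proj_b"]
    idx = np.arange(T)[:, None] + np.arange(W)[None, :]
    z = tok[:, idx] + params["pos"][None, None]          # (B, T, W, E)
    for layer in range(spec.n_layers):
        p = f"l{layer}_"
        q = anp.reshape(anp.einsum("btwe,de->btwd", z, params[p + "wq"]),
                        (B, T, W, nh, dh))
        k = anp.reshape(anp.einsum("btwe,de->btwd", z, params[p + "wk"]),
                        (B, T, W, nh, dh))
        v = anp.reshape(anp.einsum("btwe,de->btwd", z, params[p + "wv"]),
                        (B, T, W, nh, dh))
        scores = anp.einsum("btqhd,btkhd->bthqk", q, k) / np.sqrt(dh)
        att = _softmax(scores)
        ctx = anp.einsum("bthqk,btkhd->btqhd", att, v)
        ctx = anp.reshape(ctx, (B, T, W, E))
        z = layernorm(z + anp.einsum("btwe,de->btwd", ctx, params[p + "wo"]),
                      params[p + "ln1_g"], params[p + "ln1_b"])
        h = anp.maximum(anp.einsum("btwe,fe->btwf", z, params[p + "ff1_w"])
                        + params[p + "ff1_b"], 0.0)
        ff = anp.einsum("btwf,ef->btwe", h, params[p + "ff2_w"]) + params[p + "ff2_b"]
        z = layernorm(z + ff, params[p + "ln2_g"], params[p + "ln2_b"])
    pooled = anp.mean(z, axis=2)                         # (B, T, E)
    y = anp.einsum("ne,bte->bnt", params["wr"], pooled) + params["br"][None, :, None]
    if spec.output_nl:
        y = double_exponential(y, params["nl"])
    return y, None
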