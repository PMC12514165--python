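"""Stateful architectures: DNet and the StateNet family.

DNet is the recurrent variant of the NRF model: the same hidden bank of
spectro-temporal filters (fixed 5-bin input window), but each hidden unit
carries a leaky state ``h_t = (1 - lam) * h_{t-1} + lam * sig(conv)`` with a
learnable per-unit leak ``lam in (0, 1)`` — a non-spiking leaky integrator.

StateNet consumes one time bin per step: the frequency vector is downsampled
by a tonotopy-preserving locally connected (LC) layer, batch-normalized, fed
to a single recurrent core (Elman / GRU / LSTM / diagonal SSM), and the core
state is projected linearly into per-neuron rates.  The readout is linear by
default; the double-exponential output can be enabled via the model spec.

The SSM core is a minimal S4-style diagonal linear state space: continuous
dynamics ``x' = A x + B u`` with a learned negative-real diagonal ``A``,
discretized per channel by zero-order hold (``Ad = exp(A dt)``,
``Bd = (Ad - 1)/A``) with a learned step size, output ``y = C x + D u``
followed by a tanh.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .common import (batchnorm, default_nl_params, double_exponential,
                     lc_apply, lc_geometry, sigmoid, time_windows,
                     uniform_init)

DNET_WINDOW = 5


# ---------------------------------------------------------------- DNet

def init_dnet(rng, spec) -> dict:
    F, N, H = spec.n_freqs, spec.n_neurons, spec.hidden
    W = DNET_WINDOW
    params = {
        "wh": uniform_init(rng, (H, F, W), F * W),
        "bh": uniform_init(rng, (H,), F * W),
        "bn_gamma": np.ones(H),
        "bn_beta": np.zeros(H),
        "lam_raw": np.zeros(H),       # sigmoid -> leak 0.5
        "wr": uniform_init(rng, (N, H), H),
        "br": uniform_init(rng, (N,), H),
    }
    if spec.output_nl:
        params["nl"] = default_nl_params(N)
    return params


def _dnet_drive(params, x, mode, stats):
    wins = time_windows(x, DNET_WINDOW)
    z = anp.einsum("hfw,bftw->bht", params["wh"], wins) + params["bh"][None, :, None]
    z = batchnorm(z, params["bn_gamma"], params["bn_beta"], "bn_h", mode, stats)
    return sigmoid(z)


def forward_dnet(params, x, spec, mode, stats, state=None):
    B, F, T = x.shape
    s = _dnet_drive(params, x, mode, stats)        # (B, H, T)
    lam = sigmoid(params["lam_raw"])[None, :]
    h = anp.zeros((B, s.shape[1])) if state is None else state[0]
    outs = []
    for t in range(T):
        h = (1.0 - lam) * h + lam * s[:, :, t]
        outs.append(h)
    hs = anp.stack(outs, axis=2)                   # (B, H, T)
    y = anp.einsum("nh,bht->bnt", params["wr"], hs) + params["br"][None, :, None]
    if spec.output_nl:
        y = double_exponential(y, params["nl"])
    return y, (hs[:, :, -1],)


# ---------------------------------------------------------------- cores

def init_core(rng, spec) -> dict:
    H_in = lc_geometry(spec.n_freqs, spec.lc_kernel, spec.lc_stride)[0]
    n_h = spec.hidden
    core = spec.core
    p = {}
    if core == "elman":
        p["wx"] = uniform_init(rng, (n_h, H_in), n_h)
        p["wh"] = uniform_init(rng, (n_h, n_h), n_h)
        p["b"] = uniform_init(rng, (n_h,), n_h)
    elif core in ("gru", "lstm"):
        n_gates = 3 if core == "gru" else 4
        p["wi"] = uniform_init(rng, (n_gates * n_h, H_in), n_h)
        p["bi"] = uniform_init(rng, (n_gates * n_h,), n_h)
        p["wh"] = uniform_init(rng, (n_gates * n_h, n_h), n_h)
        p["bh"] = uniform_init(rng, (n_gates * n_h,), n_h)
    elif core == "ssm":
        p["a_log"] = np.log(rng.uniform(0.5, 2.0, n_h))   # A = -exp(a_log)
        p["log_dt"] = np.log(rng.uniform(0.05, 0.5, n_h))
        p["bmat"] = uniform_init(rng, (n_h, H_in), H_in)
        p["cmat"] = uniform_init(rng, (n_h, n_h), n_h)
        p["dmat"] = uniform_init(rng, (n_h, H_in), H_in)
    else:
        raise ValueError(f"unknown StateNet core {core!r}")
    return p


def zero_state(spec, batch: int, n_h: int):
    if spec.architecture == "dnet":
        return (np.zeros((batch, spec.hidden)),)
    if spec.core == "lstm":
        return (np.zeros((batch, n_h)), np.zeros((batch, n_h)))
    return (np.zeros((batch, n_h)),)


def input_proj(params, spec, u):
    """Input-to-core projections for a whole sequence, pointwise in time.

    ``u``: (B, H_in, T) -> (B, G, T) where G is the core's gate width.
    Hoisting this out of the recurrent loop keeps the per-step graph small.
    """
    core = spec.core
    if core == "elman":
        return anp.einsum("gh,bht->bgt", params["wx"], u) + params["b"][None, :, None]
    if core in ("gru", "lstm"):
        return anp.einsum("gh,bht->bgt", params["wi"], u) + params["bi"][None, :, None]
    if core == "ssm":
        drive = anp.einsum("gh,bht->bgt", params["bmat"], u)
        feed = anp.einsum("gh,bht->bgt", params["dmat"], u)
        return anp.concatenate([drive, feed], axis=1)
    raise ValueError(f"unknown StateNet core {core!r}")


def core_step_z(params, spec, z, state):
    """One recurrent update from a projected input slice ``z``: (B, G)."""
    core = spec.core
    n_h = spec.hidden
    if core == "elman":
        h = anp.tanh(z + anp.dot(state[0], params["wh"].T))
        return h, (h,)
    if core == "gru":
        h = state[0]
        gh = anp.dot(h, params["wh"].T) + params["bh"]
        rz = sigmoid(z[:, :2 * n_h] + gh[:, :2 * n_h])
        n = anp.tanh(z[:, 2 * n_h:] + rz[:, :n_h] * gh[:, 2 * n_h:])
        h_new = n + rz[:, n_h:] * (h - n)
        return h_new, (h_new,)
    if core == "lstm":
        h, c = state
        g = z + anp.dot(h, params["wh"].T) + params["bh"]
        ifo = sigmoid(anp.concatenate(
            [g[:, :2 * n_h], g[:, 3 * n_h:]], axis=1))
        gg = anp.tanh(g[:, 2 * n_h:3 * n_h])
        c_new = ifo[:, n_h:2 * n_h] * c + ifo[:, :n_h] * gg
        h_new = ifo[:, 2 * n_h:] * anp.tanh(c_new)
        return h_new, (h_new, c_new)
    if core == "ssm":
        a = -anp.exp(params["a_log"])
        ad = anp.exp(a * anp.exp(params["log_dt"]))
        bd = (ad - 1.0) / a
        s_new = ad * state[0] + bd * z[:, :n_h]
        y = anp.dot(s_new, params["cmat"].T) + z[:, n_h:]
        return anp.tanh(y), (s_new,)
    raise ValueError(f"unknown StateNet core {core!r}")


def core_step(params, spec, u, state):
    """One recurrent update.  ``u``: (B, H_in); returns (out (B, n_h), state')."""
    z = input_proj(params, spec, u[:, :, None])[:, :, 0]
    return core_step_z(params, spec, z, state)


def ssm_linear_scan(a_log, log_dt, bmat, cmat, dmat, u):
    """The raw (pre-tanh) diagonal state-space recurrence.

    ``u``: (T, H_in) input sequence; returns (T, n_h) outputs of the
    zero-order-hold discretization of ``x' = A x + B u``, ``y = C x + D u``
    with ``A = diag(-exp(a_log))`` and per-channel step ``dt = exp(log_dt)``.
    Exposed separately so it can be checked against a naive matrix-exponential
    integration of the continuous system.
    """
    a = -np.exp(a_log)
    dt = np.exp(log_dt)
    ad = np.exp(a * dt)
    bd = (ad - 1.0) / a
    s = np.zeros(a.shape[0])
    ys = []
    for t in range(u.shape[0]):
        s = ad * s + bd * (bmat @ u[t])
        ys.append(cmat @ s + dmat @ u[t])
    return np.stack(ys)


# ---------------------------------------------------------------- StateNet

def init_statenet(rng, spec) -> dict:
    F, N = spec.n_freqs, spec.n_neurons
    H, _ = lc_geometry(F, spec.lc_kernel, spec.lc_stride)
    params = {
        "lc_w": uniform_init(rng, (H, spec.lc_kernel), spec.lc_kernel),
        "lc_b": uniform_init(rng, (H,), spec.lc_kernel),
        "bn_gamma": np.ones(H),
        "bn_beta": np.zeros(H),
        "wr": uniform_init(rng, (N, spec.hidden), spec.hidden),
        "br": uniform_init(rng, (N,), spec.hidden),
    }
    params.update(init_core(rng, spec))
    if spec.output_nl:
        params["nl"] = default_nl_params(N)
    return params


def lc_bn(params, x, spec, mode, stats):
    """LC downsampling + BN, pointwise in time: (B, F, T) -> (B, H, T)."""
    u = lc_apply(x, params["lc_w"], params["lc_b"], spec.lc_stride)
    return batchnorm(u, params["bn_gamma"], params["bn_beta"], "bn_lc",
                     mode, stats)


def readout(params, spec, core_out):
    """Linear projection of core outputs into per-neuron rates.

    ``core_out``: (B, n_h) or (B, n_h, T); returns (B, N) or (B, N, T).
    """
    if core_out.ndim == 2:
        y = anp.dot(core_out, params["wr"].T) + params["br"]
        if spec.output_nl:
            y = double_exponential(y[:, :, None], params["nl"])[:, :, 0]
        return y
    y = anp.einsum("nh,bht->bnt", params["wr"], core_out) + params["br"][None, :, None]
    if spec.output_nl:
        y = double_exponential(y, params["nl"])
    return y


def forward_statenet(params, x, spec, mode, stats, state=None):
    B, F, T = x.shape
    u = lc_bn(params, x, spec, mode, stats)        # (B, H, T)
    if state is None:
        state = zero_state(spec, B, spec.hidden)
    z = input_proj(params, spec, u)                # (B, G, T)
    outs = []
    for t in range(T):
        out, state = core_step_z(params, spec, z[:, :, t], state)
        outs.append(out)
    core_out = anp.stack(outs, axis=2)             # (B, n_h, T)
    return readout(params, spec, core_out), state


def segment_scan(params, spec, z_seg, h0, mask):
    """Run K masked core steps on a batch of segments; return final outputs.

    ``z_seg``: (S, G, K) per-segment projected inputs (see ``input_proj``);
    ``h0``: initial state tuple with leading dimension S; ``mask``: (S, K),
    1 where the step is inside the sequence (masked steps leave the state
    unchanged).  Used by truncated backpropagation through time, where each
    loss bin gets its own K-step segment.
    """
    S, _, K = z_seg.shape
    state = h0
    out = None
    for j in range(K):
        m = mask[:, j][:, None]
        new_out, new_state = core_step_z(params, spec, z_seg[:, :, j], state)
        state = tuple(m * ns + (1.0 - m) * s for ns, s in zip(new_state, state))
        out = new_out if out is None else m * new_out + (1.0 - m) * out
    return out
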