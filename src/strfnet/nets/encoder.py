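"""Model specification and the causal-encoder contract.

Every architecture is a causal, differentiable map from an ``F x T``
cochleagram to an ``N x T`` matrix of predicted rates: output bin ``t``
depends only on input bins ``<= t``.  Stateless architectures read a finite
temporal window of ``trf_bins`` past bins; stateful ones (DNet, StateNet)
consume a short fixed window (5 bins for DNet, a single bin for StateNet)
and carry a hidden state, which defaults to zero at the sequence start.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import recurrent, stateless, transformer
from .common import lc_geometry

ARCHITECTURES = ("linear", "ln", "nrf", "dnet", "cnn2d", "transformer",
                 "statenet")
CORES = ("elman", "gru", "lstm", "ssm")
STATEFUL = ("dnet", "statenet")


@dataclass
class ModelSpec:
    """Everything needed to build an encoder deterministically.

    ``output_nl=None`` resolves to the architecture's convention: the
    double-exponential output is used by all stateless models except the
    purely linear one and by the Transformer, while StateNet reads out
    linearly from its state vector.
    """

    architecture: str
    n_freqs: int
    n_neurons: int
    trf_bins: int = 10
    hidden: int = 16
    core: str = "gru"
    lc_kernel: int = 3
    lc_stride: int = 2
    embed_dim: int = 48
    n_heads: int = 4
    n_layers: int = 1
    cnn_channels: int = 10
    cnn_layers: int = 2
    cnn_kernel: tuple[int, int] = (3, 3)
    output_nl: bool | None = None
    use_bn: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "statenet" and self.core not in CORES:
            raise ValueError(f"unknown StateNet core {self.core!r}")
        if self.architecture not in STATEFUL and self.trf_bins < 1:
            raise ValueError("stateless architectures require trf_bins >= 1")
        if self.n_freqs < 1 or self.n_neurons < 1:
            raise ValueError("n_freqs and n_neurons must be >= 1")
        self.cnn_kernel = tuple(self.cnn_kernel)
        if self.output_nl is None:
            self.output_nl = self.architecture in ("ln", "nrf", "dnet",
                                                   "cnn2d", "transformer")

    @property
    def window(self) -> int | None:
        """Explicit temporal input window in bins (None = unbounded memory)."""
        if self.architecture in ("linear", "ln", "nrf", "transformer"):
            return self.trf_bins
        if self.architecture == "cnn2d":
            return stateless.cnn2d_window(self)
        return None  # dnet / statenet: stateful, unbounded

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


_INIT = {
    "linear": stateless.init_linear,
    "ln": stateless.init_linear,
    "nrf": stateless.init_nrf,
    "dnet": recurrent.init_dnet,
    "cnn2d": stateless.init_cnn2d,
    "transformer": transformer.init_transformer,
    "statenet": recurrent.init_statenet,
}

_FORWARD = {
    "linear": stateless.forward_linear,
    "ln": stateless.forward_linear,
    "nrf": stateless.forward_nrf,
    "dnet": recurrent.forward_dnet,
    "cnn2d": stateless.forward_cnn2d,
    "transformer": transformer.forward_transformer,
    "statenet": recurrent.forward_statenet,
}


class CausalEncoder:
    """A built encoder: spec + parameter dict + frozen BN statistics."""

    def __init__(self, spec: ModelSpec, params: dict, bn_stats: dict | None = None):
        self.spec = spec
        self.params = params
        self.bn_stats = bn_stats if bn_stats is not None else {}

    # -------------------------------------------------------------- forward
    def forward(self, x, params: dict | None = None, state=None,
                mode: str = "eval", return_state: bool = False):
        """Predict rates for a cochleagram (F, T) or batch (B, F, T).

        ``params`` may override the stored parameters (used by autograd,
        which differentiates through this call).  ``state`` is the carried
        hidden state for stateful models (default: zeros).
        """
        params = self.params if params is None else params
        arr = x.values if hasattr(x, "values") and hasattr(x, "freqs") else x
        single = arr.ndim == 2
        xb = arr[None] if single else arr
        if xb.shape[1] != self.spec.n_freqs:
            raise ValueError(
                f"model expects F={self.spec.n_freqs}, got {xb.shape[1]}")
        y, new_state = _FORWARD[self.spec.architecture](
            params, xb, self.spec, mode, self.bn_stats, state)
        if single:
            y = y[0]
        return (y, new_state) if return_state else y

    def step(self, x_t, state=None, params: dict | None = None):
        """Advance a stateful model by one bin.

        ``x_t``: frequency vector (F,) or batch (B, F).  Returns
        (rates (N,) or (B, N), new state).  ``state=None`` starts from the
        default zero state, so iterating over t reproduces ``forward``.
        """
        if not self.is_stateful:
            raise ValueError("step() requires a stateful model")
        params = self.params if params is None else params
        x_t = np.asarray(x_t, dtype=float)
        single = x_t.ndim == 1
        xb = x_t[None] if single else x_t
        B = xb.shape[0]
        spec = self.spec
        if spec.architecture == "statenet":
            if state is None:
                state = recurrent.zero_state(spec, B, spec.hidden)
            self._check_state(state, B)
            u = recurrent.lc_bn(params, xb[:, :, None], spec, "eval",
                                self.bn_stats)[:, :, 0]
            out, new_state = recurrent.core_step(params, spec, u, state)
            rates = recurrent.readout(params, spec, out)
        else:  # dnet: state = (leaky h, buffer of the last W-1 input bins)
            W = recurrent.DNET_WINDOW
            if state is None:
                state = (np.zeros((B, spec.hidden)),
                         np.zeros((B, spec.n_freqs, W - 1)))
            h, buf = state
            if np.shape(h) != (B, spec.hidden) or np.shape(buf) != (B, spec.n_freqs, W - 1):
                raise ValueError("hidden state shape does not match the core")
            xwin = np.concatenate([buf, xb[:, :, None]], axis=2)
            from .common import batchnorm as _bn, sigmoid as _sig
            z = np.einsum("hfw,bfw->bh", params["wh"], xwin) + params["bh"]
            zz = _bn(z[:, :, None], params["bn_gamma"], params["bn_beta"],
                     "bn_h", "eval", self.bn_stats)[:, :, 0]
            s = _sig(zz)
            lam = _sig(params["lam_raw"])[None, :]
            h_new = (1.0 - lam) * h + lam * s
            rates = np.dot(h_new, params["wr"].T) + params["br"]
            if spec.output_nl:
                from .common import double_exponential as _de
                rates = _de(rates[:, :, None], params["nl"])[:, :, 0]
            new_state = (h_new, xwin[:, :, 1:])
        if single:
            rates = rates[0]
        return rates, new_state

    def _check_state(self, state, batch: int) -> None:
        expected = recurrent.zero_state(self.spec, batch, self.spec.hidden)
        if len(state) != len(expected) or any(
                np.shape(s) != e.shape for s, e in zip(state, expected)):
            raise ValueError("hidden state shape does not match the core")

    # -------------------------------------------------------------- misc
    @property
    def is_stateful(self) -> bool:
        return self.spec.architecture in STATEFUL

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy(self) -> "CausalEncoder":
        return CausalEncoder(self.spec, copy.deepcopy(self.params),
                             copy.deepcopy(self.bn_stats))

    # -------------------------------------------------------------- storage
    def save(self, path, meta: dict | None = None) -> None:
        """Checkpoint: spec + parameters + BN stats + metadata (npz, v1)."""
        payload = {f"param:{k}": v for k, v in self.params.items()}
        for k, (m, v) in self.bn_stats.items():
            payload[f"bnstat:{k}:mean"] = m
            payload[f"bnstat:{k}:var"] = v
        payload["__spec__"] = np.frombuffer(
            json.dumps(self.spec.to_dict()).encode(), dtype=np.uint8)
        payload["__meta__"] = np.frombuffer(
            json.dumps(meta or {}).encode(), dtype=np.uint8)
        payload["__version__"] = np.array([1])
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "CausalEncoder":
        with np.load(path) as f:
            spec = ModelSpec.from_dict(
                json.loads(bytes(f["__spec__"]).decode()))
            params = {k[6:]: f[k] for k in f.files if k.startswith("param:")}
            stats: dict = {}
            for k in f.files:
                if k.startswith("bnstat:") and k.endswith(":mean"):
                    name = k[7:-5]
                    stats[name] = (f[k], f[f"bnstat:{name}:var"])
        return cls(spec, params, stats)


def build_model(spec: ModelSpec) -> CausalEncoder:
    """Construct an encoder with seed-deterministic initial parameters."""
    rng = np.random.default_rng(spec.seed)
    params = _INIT[spec.architecture](rng, spec)
    return CausalEncoder(spec, params)


def statenet_step(model: CausalEncoder, x_t, state=None):
    """Functional alias for :meth:`CausalEncoder.step`."""
    return model.step(x_t, state)
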