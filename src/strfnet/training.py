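"""The neural-response-fitting task.

Models are trained to minimize the mean squared error between predicted
rates and the recorded PSTH, with Adam(W) updates (betas 0.9/0.999, constant
learning rate 1e-3), a clip-level train/valid/test split, per-epoch
validation, checkpointing on improvement and early stopping after a fixed
patience.  No weight decay, dropout or augmentation is used.

Stateful models can alternatively be trained with truncated backpropagation
through time, TBPTT(K1=1, K2=K): the loss is evaluated at every bin, but the
gradient at bin ``t`` flows through at most ``K`` bins of history.  With
*warmup*, the state entering each truncated graph is the state obtained by
running the network (without gradients) from the sequence start; without
warmup the graph starts from the default zero state.  TBPTT(K=T, warmup) is
exactly full BPTT.

Batch normalization uses frozen running statistics inside every
differentiated pass; the statistics are refreshed from the training set at
the start of each epoch ("refresh-then-freeze").  This keeps full-BPTT and
TBPTT gradients on identical footing and makes training deterministic given
the seeds.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import autograd
import autograd.numpy as anp
import numpy as np
import pandas as pd

from .data import EncodingDataset
from .metrics import cc_norm, cc_raw, signal_power
from .nets.encoder import CausalEncoder
from .nets import recurrent


def mse_loss(pred, target):
    """Mean over all N*T (and batch) bins of squared prediction error."""
    if anp.shape(pred) != anp.shape(target):
        raise ValueError("pred and target shapes must match")
    return anp.mean((pred - target) ** 2)


@dataclass
class TbpttConfig:
    """Truncation settings: loss every bin (K1 = 1), graph length K bins."""

    k: int
    warmup: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 1
    patience: int = 50
    max_epochs: int | None = None
    seed: int = 0
    tbptt: TbpttConfig | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class FitResult:
    """Outcome of one training run (one seed, one split)."""

    best_model: CausalEncoder
    metrics: pd.DataFrame          # rows (neuron, split) -> cc_raw, cc_norm
    history: pd.DataFrame          # per-epoch train/valid loss
    best_epoch: int
    best_val_loss: float
    seed: int
    split_labels: list[str] = field(default_factory=list)

    def mean_cc_norm(self, split: str = "test") -> float:
        sel = self.metrics[self.metrics["split"] == split]
        return float(sel["cc_norm"].mean())


# ---------------------------------------------------------------- plumbing

class _Adam:
    def __init__(self, params: dict, lr: float, betas: tuple[float, float]):
        self.lr = lr
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + 1e-8)
        return out


def _split_batches(dataset: EncodingDataset, split: str, batch_size: int):
    """Group same-length clips of a split into (x, y) batches."""
    clips = dataset.clips_in(split)
    if not clips:
        raise ValueError(f"split {split!r} is empty")
    by_len: dict[int, list] = {}
    for clip in clips:
        by_len.setdefault(clip.cochleagram.n_bins, []).append(clip)
    batches = []
    for group in by_len.values():
        for i in range(0, len(group), batch_size):
            chunk = group[i:i + batch_size]
            x = np.stack([c.cochleagram.values for c in chunk])
            y = np.stack([
                np.stack([c.responses[n].psth for n in dataset.neurons])
                for c in chunk])
            batches.append((x, y))
    return batches


def evaluate(model: CausalEncoder, dataset: EncodingDataset,
             split: str) -> pd.DataFrame:
    """Per-neuron CC_raw / CC_norm on one split.

    All clips of the split are concatenated temporally into one long sequence
    before computing the metrics (predictions are still produced per clip,
    each starting from the default state).  If trial counts differ across
    clips, trials are truncated to the smallest count for the concatenation.
    """
    clips = dataset.clips_in(split)
    if not clips:
        raise ValueError(f"split {split!r} is empty")
    preds, psths, trial_blocks = [], [], []
    for clip in clips:
        preds.append(np.asarray(model.forward(clip.cochleagram.values)))
        psths.append(np.stack([clip.responses[n].psth for n in dataset.neurons]))
        trial_blocks.append([clip.responses[n].trials for n in dataset.neurons])
    pred = np.concatenate(preds, axis=1)
    psth = np.concatenate(psths, axis=1)
    m_min = min(tb[0].shape[0] for tb in trial_blocks)
    rows = []
    for i, neuron in enumerate(dataset.neurons):
        trials = np.concatenate([tb[i][:m_min] for tb in trial_blocks], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = signal_power(trials) if m_min >= 2 else np.var(trials[0])
            rows.append({
                "neuron": neuron, "split": split,
                "cc_raw": cc_raw(pred[i], psth[i]),
                "cc_norm": cc_norm(pred[i], trials),
                "signal_power": sp,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- fitting

def _bn_refresh(model: CausalEncoder, batches) -> None:
    """Recompute frozen BN statistics from the training set (no gradients)."""
    if not any(k.startswith("bn") for k in model.params):
        return
    x_all = batches[0][0] if len(batches) == 1 else None
    if x_all is not None:
        model.forward(x_all, mode="refresh")
        return
    # different clip lengths: concatenate along time for the statistics
    flat = np.concatenate(
        [x.transpose(1, 0, 2).reshape(x.shape[1], -1) for x, _ in batches],
        axis=1)
    model.forward(flat[None], mode="refresh")


def _fit_loop(model, dataset, config, loss_and_grad) -> FitResult:
    if dataset.split_labels is None:
        raise ValueError("dataset has no split labels; call split_dataset first")
    if model.spec.n_neurons != dataset.n_neurons:
        raise ValueError("model N does not match the dataset")
    rng = np.random.default_rng(config.seed)
    train_batches = _split_batches(dataset, "train", config.batch_size)
    valid_batches = _split_batches(dataset, "valid", 1_000_000)

    opt = _Adam(model.params, config.lr, config.betas)
    best = {"params": copy.deepcopy(model.params),
            "stats": copy.deepcopy(model.bn_stats),
            "epoch": -1, "val": np.inf}
    history = []
    epochs_since_improvement = 0
    epoch = 0
    while True:
        _bn_refresh(model, train_batches)
        order = rng.permutation(len(train_batches))
        train_losses = []
        for bi in order:
            x, y = train_batches[bi]
            loss, grads = loss_and_grad(model, x, y)
            train_losses.append(loss)
            model.params = opt.step(model.params, grads)
        val_losses = [float(mse_loss(model.forward(x), y))
                      for x, y in valid_batches]
        val = float(np.mean(val_losses))
        improved = val < best["val"]
        if improved:
            best = {"params": copy.deepcopy(model.params),
                    "stats": copy.deepcopy(model.bn_stats),
                    "epoch": epoch, "val": val}
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
        history.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                        "valid_loss": val, "improved": improved})
        epoch += 1
        if epochs_since_improvement >= config.patience:
            break
        if config.max_epochs is not None and epoch >= config.max_epochs:
            break

    model.params = best["params"]
    model.bn_stats = best["stats"]
    metrics = pd.concat([evaluate(model, dataset, s)
                         for s in ("train", "valid", "test")],
                        ignore_index=True)
    return FitResult(best_model=model.copy(), metrics=metrics,
                     history=pd.DataFrame(history), best_epoch=best["epoch"],
                     best_val_loss=best["val"], seed=config.seed,
                     split_labels=list(dataset.split_labels))


def fit(model: CausalEncoder, dataset: EncodingDataset,
        config: TrainConfig | None = None) -> FitResult:
    """Train with full backpropagation (through time, for stateful models)."""
    config = config or TrainConfig()
    if config.tbptt is not None:
        return tbptt_fit(model, dataset, config)

    def loss_fn(params, model_, x, y):
        return mse_loss(model_.forward(x, params=params), y)

    vag = autograd.value_and_grad(loss_fn)

    def loss_and_grad(model_, x, y):
        loss, grads = vag(model_.params, model_, x, y)
        return float(loss), grads

    return _fit_loop(model, dataset, config, loss_and_grad)


# ---------------------------------------------------------------- TBPTT

def _scan_states(model: CausalEncoder, x: np.ndarray):
    """State trajectory without gradients: states[t] = state before bin t."""
    spec = model.spec
    u = np.asarray(recurrent.lc_bn(model.params, x, spec, "eval",
                                   model.bn_stats))
    B, _, T = u.shape
    state = recurrent.zero_state(spec, B, spec.hidden)
    per_tensor = [[s] for s in state]
    for t in range(T):
        _, state = recurrent.core_step(model.params, spec, u[:, :, t], state)
        for lst, s in zip(per_tensor, state):
            lst.append(np.asarray(s))
    return [np.stack(lst) for lst in per_tensor]   # each (T+1, B, n_h)


def tbptt_loss(model: CausalEncoder, params: dict, x: np.ndarray,
               y: np.ndarray, k: int, warmup: bool, states_all=None):
    """TBPTT(K1=1, K2=k) training loss for a StateNet.

    Every bin ``t`` contributes a loss term whose graph covers bins
    ``max(0, t-k+1) .. t``; the state entering the graph is the no-gradient
    forward state (warmup) or the zero state (no warmup).  Implemented by
    batching the per-bin truncated segments, so the cost is K masked steps on
    a (B*T)-wide batch rather than T separate graphs.
    """
    spec = model.spec
    B, _, T = x.shape
    K = min(k, T)
    u = recurrent.lc_bn(params, x, spec, "eval", model.bn_stats)   # (B,H,T)
    z = recurrent.input_proj(params, spec, u)                      # (B,G,T)
    idx = np.arange(T)[:, None] - (K - 1) + np.arange(K)[None, :]  # (T,K)
    mask = (idx >= 0).astype(float)
    idxc = np.clip(idx, 0, None)
    zseg = anp.reshape(anp.transpose(z[:, :, idxc], (0, 2, 1, 3)),
                       (B * T, z.shape[1], K))
    starts = np.maximum(idx[:, 0], 0)                              # (T,)
    if warmup:
        if states_all is None:
            states_all = _scan_states(model, x)
        h0 = tuple(
            anp.reshape(anp.transpose(sa[starts], (1, 0, 2)), (B * T, -1))
            for sa in states_all)
    else:
        h0 = tuple(anp.zeros((B * T, s.shape[-1]))
                   for s in recurrent.zero_state(spec, 1, spec.hidden))
    out = recurrent.segment_scan(params, spec, zseg, h0, np.tile(mask, (B, 1)))
    rates = recurrent.readout(params, spec, out)                   # (B*T, N)
    target = anp.reshape(anp.transpose(y, (0, 2, 1)), (B * T, -1))
    return anp.mean((rates - target) ** 2)


def tbptt_fit(model: CausalEncoder, dataset: EncodingDataset,
              config: TrainConfig) -> FitResult:
    """Train a stateful model with truncated backpropagation through time."""
    if config.tbptt is None:
        raise ValueError("config.tbptt must be set for tbptt_fit")
    if model.spec.architecture != "statenet":
        raise ValueError("TBPTT training requires a stateful StateNet model")
    k, warmup = config.tbptt.k, config.tbptt.warmup

    vag = autograd.value_and_grad(tbptt_loss, argnum=1)

    def loss_and_grad(model_, x, y):
        states = _scan_states(model_, x) if warmup else None
        loss, grads = vag(model_, model_.params, x, y, k, warmup, states)
        return float(loss), grads

    return _fit_loop(model, dataset, config, loss_and_grad)


def single_unit_view(dataset: EncodingDataset, neuron: str) -> EncodingDataset:
    """Restrict a dataset to the clips recorded for one neuron."""
    clips = [c for c in dataset.clips if neuron in c.responses]
    labels = None
    if dataset.split_labels is not None:
        labels = [s for c, s in zip(dataset.clips, dataset.split_labels)
                  if neuron in c.responses]
    return EncodingDataset(clips=clips, neurons=[neuron],
                           population_mode=True, split_labels=labels)
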