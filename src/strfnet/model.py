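"""High-level modelling interface.

``NeuralEncoding`` binds a dataset to an encoder specification; ``fit``
returns a ``NeuralEncodingResults`` carrying the trained encoder(s),
per-neuron metrics, training history, a ``summary()`` table, and the
gradient-based interpretation tools (GradMaps, Dreams, energy traces).

Example
-------
>>> stimuli = synthetic.generate_stimuli(F=16, T=400, n_clips=10, seed=0)
>>> truth = synthetic.random_ground_truth(5, F=16, W=10, seed=0)
>>> ds = synthetic.simulate_neurons(stimuli, truth, M=10)
>>> res = NeuralEncoding(ds, architecture="ln", trf_bins=10).fit(seeds=[0])
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import interpret
from .data import EncodingDataset, split_dataset
from .nets.encoder import CausalEncoder, ModelSpec, build_model
from .training import FitResult, TrainConfig, fit as _fit


class NeuralEncoding:
    """An encoding model bound to a stimulus-response dataset."""

    def __init__(self, dataset: EncodingDataset, spec: ModelSpec | None = None,
                 architecture: str = "statenet", **spec_kwargs):
        self.dataset = dataset
        if spec is None:
            spec = ModelSpec(architecture=architecture,
                             n_freqs=dataset.n_freqs,
                             n_neurons=dataset.n_neurons, **spec_kwargs)
        if spec.n_freqs != dataset.n_freqs or spec.n_neurons != dataset.n_neurons:
            raise ValueError("model spec does not match the dataset dimensions")
        self.spec = spec

    def fit(self, config: TrainConfig | None = None, seeds=None,
            split_ratios=(0.7, 0.1, 0.2), **config_kwargs
            ) -> "NeuralEncodingResults":
        """Train the model for one or several seeds.

        Each seed draws its own clip-level train/valid/test split and its
        own parameter initialization, as in repeated-seed benchmarking; test
        metrics are then averaged across seeds.
        """
        seeds = [0] if seeds is None else list(seeds)
        fits = []
        for seed in seeds:
            cfg = config if config is not None else TrainConfig(**config_kwargs)
            cfg.seed = seed
            spec = ModelSpec.from_dict({**self.spec.to_dict(), "seed": seed})
            model = build_model(spec)
            ds = (self.dataset if self.dataset.split_labels is not None
                  and len(seeds) == 1
                  else split_dataset(self.dataset, split_ratios, seed=seed))
            fits.append(_fit(model, ds, cfg))
        return NeuralEncodingResults(self, fits)


class NeuralEncodingResults:
    """Estimates, diagnostics and interpretation for a fitted encoding model."""

    def __init__(self, model: NeuralEncoding, fits: list[FitResult]):
        self.model_def = model
        self.fits = fits
        self.metrics = pd.concat(
            [f.metrics.assign(seed=f.seed) for f in fits], ignore_index=True)

    @property
    def encoder(self) -> CausalEncoder:
        """The trained encoder of the first seed."""
        return self.fits[0].best_model

    @property
    def params(self) -> dict:
        return self.encoder.params

    def mean_cc(self, split: str = "test") -> pd.Series:
        sel = self.metrics[self.metrics["split"] == split]
        return sel[["cc_raw", "cc_norm"]].mean()

    def predict(self, cochleagram) -> np.ndarray:
        return np.asarray(self.encoder.forward(cochleagram))

    # ------------------------------------------------------- interpretation
    def gradmap(self, neuron: int | str, T: int = 50, seed_index: int = 0):
        return interpret.gradmap(self.fits[seed_index].best_model,
                                 self._index(neuron), T)

    def dream(self, neuron: int | str, T: int = 50, seed_index: int = 0, **kw):
        return interpret.dream(self.fits[seed_index].best_model,
                               self._index(neuron), T, **kw)

    def _index(self, neuron: int | str) -> int:
        if isinstance(neuron, str):
            return self.model_def.dataset.neurons.index(neuron)
        return int(neuron)

    # ------------------------------------------------------- reporting
    def summary(self) -> str:
        spec = self.model_def.spec
        enc = self.encoder
        lines = [
            "Neural encoding model fit",
            "=" * 60,
            f"architecture:     {spec.architecture}"
            + (f" ({spec.core})" if spec.architecture == "statenet" else ""),
            f"neurons (N):      {spec.n_neurons}",
            f"freq bands (F):   {spec.n_freqs}",
            f"temporal window:  "
            + (f"{spec.window} bins" if spec.window else "unbounded (stateful)"),
            f"parameters:       {enc.n_params}",
            f"seeds:            {[f.seed for f in self.fits]}",
            f"epochs (best):    {[f.best_epoch for f in self.fits]}",
            "-" * 60,
        ]
        table = (self.metrics.groupby("split")[["cc_raw", "cc_norm"]]
                 .mean().reindex(["train", "valid", "test"]))
        lines.append(table.round(4).to_string())
        lines.append("-" * 60)
        lines.append("CC_norm is noise-corrected (attainable ceiling 1).")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        cc = self.mean_cc("test")
        return (f"<NeuralEncodingResults {self.model_def.spec.architecture}: "
                f"test cc_norm={cc['cc_norm']:.3f}>")
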