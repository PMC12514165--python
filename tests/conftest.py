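import numpy as np
import pytest

import strfnet as sn
from strfnet import synthetic, training


@pytest.fixture(scope="session")
def tiny_ln_dataset():
    """Small LN population with split labels, shared across test modules."""
    stimuli = synthetic.generate_stimuli(F=8, T=200, n_clips=8, seed=7)
    truth = synthetic.random_ground_truth(4, F=8, W=6, noise_sigma=0.05, seed=7)
    ds = synthetic.simulate_neurons(stimuli, truth, M=5)
    return sn.split_dataset(ds, seed=7), truth


def all_architecture_specs(F=8, N=3, trf=6, hidden=5, seed=1):
    specs = []
    for arch in ("linear", "ln", "nrf", "dnet", "cnn2d", "transformer"):
        specs.append(sn.ModelSpec(architecture=arch, n_freqs=F, n_neurons=N,
                                  trf_bins=trf, hidden=hidden, seed=seed))
    for core in ("elman", "gru", "lstm", "ssm"):
        specs.append(sn.ModelSpec(architecture="statenet", core=core,
                                  n_freqs=F, n_neurons=N, hidden=hidden,
                                  seed=seed))
    return specs


@pytest.fixture(scope="session")
def long_memory_fit():
    """A GRU StateNet trained briefly on long-memory synthetic neurons.

    Shared by the tests that probe memory beyond the stateless window
    (dream-length curves, carried-state effects).
    """
    stimuli = synthetic.generate_stimuli(F=8, T=300, n_clips=8, seed=21)
    truth = synthetic.random_ground_truth(
        4, F=8, W=6, adaptation="long_memory", tau=40.0, gamma=0.8,
        noise_sigma=0.05, seed=21)
    ds = synthetic.simulate_neurons(stimuli, truth, M=5)
    ds = sn.split_dataset(ds, seed=21)
    model = sn.build_model(sn.ModelSpec(
        architecture="statenet", core="gru", hidden=8, n_freqs=8,
        n_neurons=4, seed=21))
    result = training.fit(model, ds, training.TrainConfig(
        batch_size=8, lr=1e-2, max_epochs=80, patience=80))
    return result, ds, truth
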