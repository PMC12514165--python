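import autograd
import numpy as np
import pytest

import strfnet as sn
from strfnet import synthetic, training
from strfnet.data import Clip, EncodingDataset, NeuronRecord
from strfnet.training import (TbpttConfig, TrainConfig, evaluate, fit,
                              mse_loss, tbptt_fit, tbptt_loss)


class TestMseLoss:
    def test_examples(self):
        a = np.ones((2, 5))
        assert mse_loss(a, a) == 0.0
        assert np.isclose(mse_loss(a + 0.3, a), 0.09)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        acc = 0.0
        for i in range(2):
            for j in range(3):
                acc += (p[i, j] - t[i, j]) ** 2
        assert np.isclose(mse_loss(p, t), acc / 6.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.ones((2, 3)), np.ones((3, 2)))


def _linear_realizable_dataset(seed=0, n_clips=8, T=200, F=8, W=5, N=2):
    """Responses produced by a known linear model: exactly realizable."""
    stim = synthetic.generate_stimuli(F=F, T=T, n_clips=n_clips, seed=seed)
    truth = synthetic.random_ground_truth(N, F=F, W=W, seed=seed)
    clips = []
    for c in stim:
        resp = {}
        for n in range(N):
            d = synthetic._causal_drive(truth.strfs[n], c.values)
            resp[f"n{n:03d}"] = NeuronRecord(trials=d[None], psth=d)
        clips.append(Clip(cochleagram=c, responses=resp))
    ds = EncodingDataset(clips=clips, neurons=[f"n{n:03d}" for n in range(N)])
    return sn.split_dataset(ds, seed=seed), truth


class TestFit:
    def test_converges_on_realizable_linear_target(self):
        ds, _ = _linear_realizable_dataset()
        model = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=8,
                                            n_neurons=2, trf_bins=5))
        res = fit(model, ds, TrainConfig(batch_size=8, lr=1e-2,
                                         max_epochs=400, patience=100))
        train = res.metrics[res.metrics["split"] == "train"]
        assert (train["cc_raw"] >= 0.99).all()

    def test_early_stopping_after_exact_patience(self):
        ds, _ = _linear_realizable_dataset(n_clips=4, T=50)
        model = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=8,
                                            n_neurons=2, trf_bins=5))
        # lr=0: parameters never change, so only the first epoch improves
        res = fit(model, ds, TrainConfig(lr=1e-30, patience=5, batch_size=4))
        assert len(res.history) == 1 + 5
        assert res.best_epoch == 0

    def test_checkpoint_validation_loss_monotone(self):
        ds, _ = _linear_realizable_dataset(n_clips=6, T=100)
        model = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=8,
                                            n_neurons=2, trf_bins=5))
        res = fit(model, ds, TrainConfig(batch_size=6, lr=5e-3, max_epochs=60,
                                         patience=60))
        saved = res.history[res.history["improved"]]["valid_loss"].values
        assert np.all(np.diff(saved) <= 0)

    def test_seed_determinism(self):
        ds, _ = _linear_realizable_dataset(n_clips=4, T=60)
        def one():
            model = sn.build_model(sn.ModelSpec(architecture="nrf", n_freqs=8,
                                                n_neurons=2, trf_bins=5,
                                                hidden=3, seed=4))
            return fit(model, ds, TrainConfig(seed=4, max_epochs=10,
                                              patience=10, batch_size=2))
        a, b = one(), one()
        for k in a.best_model.params:
            assert np.array_equal(a.best_model.params[k],
                                  b.best_model.params[k])
        assert a.metrics.equals(b.metrics)

    def test_missing_splits_rejected(self):
        stim = synthetic.generate_stimuli(F=4, T=30, n_clips=3, seed=1)
        truth = synthetic.random_ground_truth(1, F=4, W=3, seed=1)
        ds = synthetic.simulate_neurons(stim, truth, M=1)
        model = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=4,
                                            n_neurons=1, trf_bins=3))
        with pytest.raises(ValueError):
            fit(model, ds, TrainConfig())


class TestGradientCorrectness:
    def test_full_pipeline_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 5, 12))
        y = rng.normal(size=(1, 2, 12))
        m = sn.build_model(sn.ModelSpec(architecture="statenet", core="gru",
                                        n_freqs=5, n_neurons=2, hidden=3,
                                        seed=2))
        loss = lambda p: mse_loss(m.forward(x, params=p), y)
        grads = autograd.grad(loss)(m.params)
        h = 1e-6
        for key in ("wr", "wi", "lc_w"):
            flat_idx = (0,) * m.params[key].ndim
            p_plus = {k: v.copy() for k, v in m.params.items()}
            p_plus[key][flat_idx] += h
            p_minus = {k: v.copy() for k, v in m.params.items()}
            p_minus[key][flat_idx] -= h
            fd = (loss(p_plus) - loss(p_minus)) / (2 * h)
            assert np.isclose(grads[key][flat_idx], fd, rtol=1e-4)


class TestTbptt:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 5, 30))
        y = rng.normal(size=(2, 2, 30))
        m = sn.build_model(sn.ModelSpec(architecture="statenet", core="gru",
                                        n_freqs=5, n_neurons=2, hidden=4,
                                        seed=3))
        return m, x, y

    def test_k_equals_t_with_warmup_is_full_bptt(self, setup):
        m, x, y = setup
        g_full = autograd.grad(
            lambda p: mse_loss(m.forward(x, params=p), y))(m.params)
        states = training._scan_states(m, x)
        g_tb = autograd.grad(
            lambda p: tbptt_loss(m, p, x, y, k=30, warmup=True,
                                 states_all=states))(m.params)
        for k in g_full:
            assert np.abs(g_full[k] - g_tb[k]).max() < 1e-6

    def test_k1_no_warmup_is_memoryless(self, setup):
        """With K=1 and no warmup each bin is an independent one-step problem."""
        m, x, y = setup
        g_tb = autograd.grad(
            lambda p: tbptt_loss(m, p, x, y, k=1, warmup=False))(m.params)

        def memoryless_loss(params):
            from strfnet.nets import recurrent
            u = recurrent.lc_bn(params, x, m.spec, "eval", m.bn_stats)
            B, H, T = u.shape
            z = recurrent.input_proj(params, m.spec, u)
            flat = np.transpose(z, (0, 2, 1)).reshape(B * T, -1)
            h0 = tuple(np.zeros((B * T, 4))
                       for _ in recurrent.zero_state(m.spec, 1, 4))
            out, _ = recurrent.core_step_z(params, m.spec, flat, h0)
            rates = recurrent.readout(params, m.spec, out)
            target = np.transpose(y, (0, 2, 1)).reshape(B * T, -1)
            import autograd.numpy as anp
            return anp.mean((rates - target) ** 2)

        g_oracle = autograd.grad(memoryless_loss)(m.params)
        for k in g_tb:
            assert np.abs(g_tb[k] - g_oracle[k]).max() < 1e-10

    def test_stateless_model_rejected(self):
        ds, _ = _linear_realizable_dataset(n_clips=4, T=40)
        m = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=8,
                                        n_neurons=2, trf_bins=5))
        with pytest.raises(ValueError):
            tbptt_fit(m, ds, TrainConfig(tbptt=TbpttConfig(k=5)))


class TestEvaluate:
    def test_perfect_model_scores_one(self):
        # dataset whose responses ARE the model's own outputs
        m = sn.build_model(sn.ModelSpec(architecture="ln", n_freqs=6,
                                        n_neurons=2, trf_bins=4, seed=5))
        stim = synthetic.generate_stimuli(F=6, T=100, n_clips=4, seed=5)
        clips = []
        for c in stim:
            pred = np.asarray(m.forward(c.values))
            resp = {f"n{n:03d}": NeuronRecord(trials=pred[n][None],
                                              psth=pred[n])
                    for n in range(2)}
            clips.append(Clip(cochleagram=c, responses=resp))
        ds = EncodingDataset(clips=clips, neurons=["n000", "n001"])
        ds = sn.split_dataset(ds, seed=5)
        table = evaluate(m, ds, "test")
        assert np.allclose(table["cc_raw"], 1.0)
        assert np.allclose(table["cc_norm"], 1.0)

    def test_constant_prediction_scores_zero(self):
        stim = synthetic.generate_stimuli(F=6, T=80, n_clips=4, seed=6)
        truth = synthetic.random_ground_truth(1, F=6, W=4, noise_sigma=0.1,
                                              seed=6)
        ds = synthetic.simulate_neurons(stim, truth, M=3)
        ds = sn.split_dataset(ds, seed=6)
        m = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=6,
                                        n_neurons=1, trf_bins=4))
        m.params["w"] = np.zeros_like(m.params["w"])
        table = evaluate(m, ds, "test")
        assert (table["cc_raw"] == 0.0).all()
        assert (table["cc_norm"] == 0.0).all()

    def test_concatenation_differs_from_per_clip_mean(self):
        # two clips whose per-clip correlations are both 1 but whose
        # concatenated correlation is not (offset between clips)
        from strfnet.metrics import cc_raw
        pred1, psth1 = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        pred2, psth2 = np.array([0.0, 1.0]), np.array([10.0, 11.0])
        per_clip = np.mean([cc_raw(pred1, psth1), cc_raw(pred2, psth2)])
        concat = cc_raw(np.concatenate([pred1, pred2]),
                        np.concatenate([psth1, psth2]))
        assert not np.isclose(per_clip, concat)

    def test_empty_split_rejected(self):
        ds, _ = _linear_realizable_dataset(n_clips=4, T=40)
        ds.split_labels = ["train"] * 4
        m = sn.build_model(sn.ModelSpec(architecture="linear", n_freqs=8,
                                        n_neurons=2, trf_bins=5))
        with pytest.raises(ValueError):
            evaluate(m, ds, "test")
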