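"""Optimization protocol: plateau rules, no-shuffle batching, checkpointing,
ensembling and learning on separable synthetic data."""

import numpy as np
import pytest

from mtlscreen.mtl_model import ModelConfig, MTLNetwork, SingleTaskNetwork, mtl_loss
from mtlscreen.training import (
    EncodedPairs,
    PlateauController,
    TrainConfig,
    predict_ensemble,
    predict_single_task_ensemble,
    train_ensemble,
    train_mtl,
    train_single_task,
)

CFG = dict(vocab_size=30, max_len=12, embed_dim=6, n_filters=4, dense_units=5)


def make_pairs(rng, n=24, vocab=30, max_len=12, separable=True):
    """Class-aligned pair data; positives use tokens 20-29, negatives 2-11."""
    y = np.array([i % 2 for i in range(n)])
    def draw(label):
        lo, hi = (20, 30) if (label and separable) else (2, 12)
        return rng.integers(lo, hi, max_len)
    X_s = np.stack([draw(l) for l in y])
    X_m = np.stack([draw(l) for l in y])
    return EncodedPairs(X_s=X_s, X_m=X_m, y_s=y, y_m=y)


class TestPlateauController:
    def run_trace(self, trace, **kw):
        ctrl = PlateauController(**kw)
        lr = 1e-3
        events = []
        for loss in trace:
            improved, lr, stop = ctrl.update(loss, lr)
            events.append((improved, lr, stop))
            if stop:
                break
        return events

    def test_constant_loss_stops_after_patience(self):
        """First epoch sets the best; three non-improving epochs stop at epoch 4."""
        events = self.run_trace([1.0] * 10)
        assert len(events) == 4
        assert events[0][0] is True and events[-1][2] is True

    def test_lr_drops_by_factor_after_two_bad_epochs(self):
        events = self.run_trace([1.0, 1.0, 1.0])
        assert events[1][1] == pytest.approx(1e-3)   # one bad epoch: no change
        assert events[2][1] == pytest.approx(1e-4)   # two bad epochs: x0.1

    def test_min_lr_floor(self):
        events = self.run_trace([1.0] * 20, early_patience=50, min_lr=1e-8)
        assert events[-1][1] >= 1e-8
        assert min(e[1] for e in events) == pytest.approx(1e-8)

    def test_improvement_resets_both_counters(self):
        events = self.run_trace([1.0, 0.9, 0.95, 0.95, 0.8, 0.85, 0.85, 0.85])
        # improvements at epochs 1, 2, 5; stop 3 bad epochs after epoch 5
        assert [e[0] for e in events] == [True, True, False, False, True, False, False, False]
        assert events[-1][2] is True

    def test_sub_delta_improvement_does_not_count(self):
        events = self.run_trace([1.0, 1.0 - 1e-9, 1.0 - 2e-9, 1.0 - 3e-9])
        assert len(events) == 4 and events[-1][2] is True


class TestTrainMtl:
    def _train(self, rng, cfg_over=None, **train_over):
        data = make_pairs(rng)
        net = MTLNetwork(ModelConfig(**{**CFG, **(cfg_over or {})}), seed=0)
        cfg = TrainConfig(max_epochs=4, batch_size=8, seed=1, **train_over)
        train, val = data.subset(np.arange(16)), data.subset(np.arange(16, 24))
        return train_mtl(net, (train, val), cfg), (train, val)

    def test_history_invariants(self, rng):
        (net, hist), _ = self._train(rng)
        assert hist.best_epoch >= 1
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)
        assert len(hist.val_loss) == hist.stopped_epoch

    def test_batches_never_reshuffled(self, rng):
        (net, hist), _ = self._train(rng)
        assert len(set(hist.batch_hashes)) == 1

    def test_best_weights_restored(self, rng):
        (net, hist), (_, val) = self._train(rng)
        p_s, p_m, v_s, v_m = net.forward(val.X_s, val.X_m, train=False)
        revalidated = mtl_loss(val.y_s, p_s, val.y_m, p_m, v_s, v_m,
                               net.config.soft_share_weight).total
        assert revalidated == pytest.approx(min(hist.val_loss), rel=1e-5)

    def test_bit_stable_given_seeds(self, rng):
        data = make_pairs(np.random.default_rng(7))
        cfg = TrainConfig(max_epochs=3, batch_size=8, seed=5)
        split = (data.subset(np.arange(16)), data.subset(np.arange(16, 24)))
        runs = []
        for _ in range(2):
            net = MTLNetwork(ModelConfig(**CFG), seed=3)
            _, hist = train_mtl(net, split, cfg)
            runs.append(hist.val_loss)
        assert runs[0] == runs[1]

    def test_learns_separable_data(self):
        """On separable synthetic pairs, validation loss drops across seeds."""
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            data = make_pairs(rng, n=40)
            net = MTLNetwork(ModelConfig(**CFG), seed=seed)
            split = (data.subset(np.arange(32)), data.subset(np.arange(32, 40)))
            # initial validation loss before any training
            p_s, p_m, v_s, v_m = net.forward(split[1].X_s, split[1].X_m, train=False)
            initial = mtl_loss(split[1].y_s, p_s, split[1].y_m, p_m, v_s, v_m,
                               net.config.soft_share_weight).total
            _, hist = train_mtl(net, split, TrainConfig(max_epochs=6, batch_size=8, seed=seed))
            assert min(hist.val_loss) < initial

    def test_empty_split_rejected(self, rng):
        data = make_pairs(rng)
        net = MTLNetwork(ModelConfig(**CFG), seed=0)
        with pytest.raises(ValueError):
            train_mtl(net, (data.subset(np.arange(0)), data), TrainConfig())


class TestSingleTask:
    def test_same_stopping_rules(self, rng):
        data = make_pairs(rng, n=24)
        net = SingleTaskNetwork(ModelConfig(**CFG), seed=0)
        cfg = TrainConfig(max_epochs=8, batch_size=8, seed=2)
        _, hist = train_single_task(
            net, ((data.X_s[:16], data.y_s[:16]), (data.X_s[16:], data.y_s[16:])), cfg
        )
        assert hist.best_epoch >= 1
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)
        assert len(set(hist.batch_hashes)) == 1

    def test_beats_chance_on_separable_data(self):
        rng = np.random.default_rng(3)
        data = make_pairs(rng, n=60)
        net = SingleTaskNetwork(ModelConfig(**CFG), seed=3)
        net, _ = train_single_task(
            net, ((data.X_s[:40], data.y_s[:40]), (data.X_s[40:], data.y_s[40:])),
            TrainConfig(max_epochs=8, batch_size=8, seed=3),
        )
        acc = (net.forward(data.X_s[40:], train=False).argmax(1) == data.y_s[40:]).mean()
        assert acc > 0.7


class TestEnsemble:
    def _splits(self, n, k):
        rng = np.random.default_rng(0)
        out = []
        for _ in range(k):
            idx = rng.permutation(n)
            out.append((idx[: int(0.8 * n)], idx[int(0.8 * n):]))
        return out

    def test_one_model_per_split_and_reproducible(self, rng):
        data = make_pairs(rng, n=30)
        cfg = TrainConfig(max_epochs=2, batch_size=8, seed=9)
        splits = self._splits(30, 3)
        models1, hists1 = train_ensemble(ModelConfig(**CFG), data, splits, cfg)
        models2, _ = train_ensemble(ModelConfig(**CFG), data, splits, cfg)
        assert len(models1) == 3
        assert models1[0].seed != models1[1].seed
        for m1, m2 in zip(models1, models2):
            p1 = m1.forward(data.X_s, data.X_m, train=False)[0]
            p2 = m2.forward(data.X_s, data.X_m, train=False)[0]
            assert np.array_equal(p1, p2)

    def test_single_split_degenerates_to_single_model(self, rng):
        data = make_pairs(rng, n=20)
        models, _ = train_ensemble(
            ModelConfig(**CFG), data, self._splits(20, 1), TrainConfig(max_epochs=2, seed=4)
        )
        assert len(models) == 1

    def test_probability_averaging(self, rng):
        data = make_pairs(rng, n=10)
        models, _ = train_ensemble(
            ModelConfig(**CFG), data, self._splits(10, 2), TrainConfig(max_epochs=1, seed=0)
        )
        pred = predict_ensemble(models, data.X_s, data.X_m)
        manual = np.mean(
            [m.forward(data.X_s, data.X_m, train=False)[0] for m in models], axis=0
        )
        assert np.allclose(pred["probs_suicide"], manual)
        assert np.allclose(pred["probs_suicide"].sum(axis=1), 1.0, atol=1e-5)
        assert ((pred["probs_suicide"] >= 0) & (pred["probs_suicide"] <= 1)).all()

    def test_k_copies_equal_single_model(self, rng):
        data = make_pairs(rng, n=10)
        net = MTLNetwork(ModelConfig(**CFG), seed=8)
        single = net.forward(data.X_s, data.X_m, train=False)[0]
        pred = predict_ensemble([net, net, net], data.X_s, data.X_m)
        assert np.allclose(pred["probs_suicide"], single, atol=1e-6)

    def test_config_mismatch_rejected(self, rng):
        data = make_pairs(rng, n=10)
        a = MTLNetwork(ModelConfig(**CFG), seed=0)
        b = MTLNetwork(ModelConfig(**{**CFG, "n_filters": 3}), seed=0)
        with pytest.raises(ValueError):
            predict_ensemble([a, b], data.X_s, data.X_m)
        sa = SingleTaskNetwork(ModelConfig(**CFG), seed=0)
        sb = SingleTaskNetwork(ModelConfig(**{**CFG, "n_filters": 3}), seed=0)
        with pytest.raises(ValueError):
            predict_single_task_ensemble([sa, sb], data.X_s)
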