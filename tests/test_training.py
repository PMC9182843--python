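"""Losses, Adam training loop, reproducibility, gradient correctness."""

import math

import numpy as np
import pytest

from msgait.backbone import BackboneConfig, LayerSpec
from msgait.network import MultiScaleGaitNet
from msgait.preprocess import InertialWindow
from msgait.synthetic import LabeledDataset, generate_dataset
from msgait.training import (TrainConfig, cross_entropy, local_loss,
                             overall_loss, train)


class TestLosses:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy(np.array([1.0, 0.0, 0.0]),
                             np.array([1.0, 0.0, 0.0])) < 1e-6

    def test_uniform_binary_is_ln2(self):
        assert cross_entropy(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == \
            pytest.approx(math.log(2.0), abs=1e-12)

    def test_batch_matches_elementwise_loop(self, rng):
        o = rng.dirichlet(np.ones(4), size=8)
        y = rng.integers(0, 4, 8)
        onehot = np.eye(4)[y]
        expected = sum(-math.log(max(o[b, y[b]], 1e-7)) for b in range(8)) / 8
        assert cross_entropy(o, onehot) == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros(3), np.zeros(4))

    def test_local_loss_selection_and_weighting(self, rng):
        onehot = np.eye(3)[rng.integers(0, 3, 5)]
        preds = [rng.dirichlet(np.ones(3), size=5) for _ in range(3)]
        # selecting one scale
        li = cross_entropy(preds[0], onehot)
        assert local_loss(preds, onehot, (1.0, 0.0, 0.0)) == \
            pytest.approx(li, abs=1e-12)
        # perfect predictions everywhere
        assert local_loss([onehot] * 3, onehot, (1 / 3,) * 3) < 1e-6
        # arbitrary weighted sum
        w = (0.2, 0.3, 0.5)
        expected = sum(a * cross_entropy(p, onehot)
                       for a, p in zip(w, preds))
        assert local_loss(preds, onehot, w) == pytest.approx(expected,
                                                             abs=1e-12)
        with pytest.raises(ValueError):
            local_loss(preds, onehot, (0.5, 0.5))

    def test_overall_loss_arithmetic(self):
        assert overall_loss(1.0, 1.0, 0.99, 0.87) == pytest.approx(1.86)
        assert overall_loss(0.0, 0.0, 0.99, 0.87) == 0.0
        assert overall_loss(2.0, 3.0, 0.5, 0.5) == pytest.approx(2.5)


def _tiny_net(n_classes=4, use_ws=True, seed=3):
    cfg = BackboneConfig(
        layers=(LayerSpec("conv", 3, 16, 1, "valid"),
                LayerSpec("maxpool", 2, 0, 2),
                LayerSpec("conv", 3, 16, 2, "same")),
        dropout_rate=0.0, l2_reg=1e-4)
    return MultiScaleGaitNet(n_classes, scales=(1, 2), input_length=30,
                             config=cfg, fused_dim=6, seed=seed,
                             fusion_dropout=0.0, use_ws=use_ws)


def _tiny_dataset(n_classes=4, n_per=6, length=30, seed=9, noise=0.0):
    rng = np.random.default_rng(seed)
    protos = rng.normal(size=(n_classes, length, 6))
    windows, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per):
            windows.append(InertialWindow(
                protos[c] + rng.normal(0, noise, (length, 6)), c))
            labels.append(c)
    return LabeledDataset(windows, np.array(labels))


class TestGradients:
    def test_backprop_matches_finite_difference(self, rng):
        """Numerical gradient of the objective w.r.t. a fusion weight (and a
        conv kernel) agrees with backprop on a tiny model."""
        net = _tiny_net()
        X = rng.normal(size=(8, 30, 6))
        y = rng.integers(0, 4, 8)
        alpha_i = (0.5, 0.5)
        # one Fisher refresh, then hold statistics fixed
        net.loss_and_grads(X, y, 0.99, 0.87, alpha_i, train=True,
                           rng=np.random.default_rng(1))

        def objective():
            losses, _ = net.loss_and_grads(X, y, 0.99, 0.87, alpha_i,
                                           train=False, update_fisher=False)
            return losses["objective"]

        _, grads = net.loss_and_grads(X, y, 0.99, 0.87, alpha_i,
                                      train=False, update_fisher=False)
        for key in ("t1.Wf", "W0", "t2.Wc", "t1.conv0_W"):
            p = net.params[key]
            idx = tuple(np.unravel_index(rng.integers(p.size), p.shape))
            eps, old = 1e-6, p[idx]
            p[idx] = old + eps
            f1 = objective()
            p[idx] = old - eps
            f2 = objective()
            p[idx] = old
            assert (f1 - f2) / (2 * eps) == pytest.approx(
                grads[key][idx], abs=1e-4), key


class TestTrainLoop:
    def test_noiseless_data_drives_local_loss_down(self):
        """On noiseless 5-class data the per-scale stack reaches a local
        loss below 0.1 within 50 epochs and perfect training rank-1."""
        ds = _tiny_dataset(n_classes=5, n_per=10)
        net = _tiny_net(n_classes=5)
        cfg = TrainConfig(learning_rate=0.003, max_epochs=50,
                          early_stop_patience=50, batch_size=4,
                          val_fraction=0.2, seed=0)
        net, hist = train(ds, net, cfg)
        probs, _ = net.predict(ds.signals())
        assert np.mean(probs.argmax(axis=1) == ds.labels) == 1.0
        assert hist.local_loss[-1] < 0.1

    def test_training_is_deterministic(self):
        ds = _tiny_dataset()
        results = []
        for _ in range(2):
            net = _tiny_net()
            cfg = TrainConfig(max_epochs=3, batch_size=8, seed=5)
            _, hist = train(ds, net, cfg)
            results.append(hist.overall_loss[-1])
        assert results[0] == pytest.approx(results[1], abs=1e-6)

    def test_single_epoch_history(self):
        net = _tiny_net()
        _, hist = train(_tiny_dataset(), net,
                        TrainConfig(max_epochs=1, batch_size=8, seed=1))
        assert hist.n_epochs() == 1
        assert len(hist.val_accuracy) == 1

    def test_missing_class_rejected(self):
        ds = _tiny_dataset(n_classes=3)
        net = _tiny_net(n_classes=4)
        with pytest.raises(ValueError, match="absent"):
            train(ds, net, TrainConfig(max_epochs=1, seed=0))

    def test_best_so_far_validation_loss_non_increasing(self):
        ds = _tiny_dataset(noise=0.3)
        net = _tiny_net()
        _, hist = train(ds, net, TrainConfig(max_epochs=10, batch_size=8,
                                             seed=2))
        best = np.minimum.accumulate(hist.val_loss)
        assert np.all(np.diff(best) <= 0.0 + 1e-12)
        assert hist.best_epoch >= 0
        assert hist.val_loss[hist.best_epoch] == pytest.approx(best[-1])

    def test_ws_ablation_changes_only_numbers_not_shapes(self):
        ds = _tiny_dataset()
        outs = {}
        for use_ws in (True, False):
            net = _tiny_net(use_ws=use_ws)
            net, _ = train(ds, net,
                           TrainConfig(max_epochs=2, batch_size=8, seed=7))
            probs, feats = net.predict(ds.signals())
            outs[use_ws] = (probs.shape, feats.shape)
            if not use_ws:
                for st in net.fisher.values():
                    assert np.array_equal(st["weights"],
                                          np.ones(net.n_prime))
        assert outs[True] == outs[False]
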