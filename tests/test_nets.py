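import numpy as np
import pytest

from octaline import nets
from octaline.nets import NetConfig

from conftest import make_aline_dataset


class TestArchitecture:
    def test_cnn_layer_lengths(self):
        lengths = nets.cnn_layer_lengths(NetConfig(arch="cnn"))
        assert lengths == {
            "padded": 210,
            "conv1": 200,
            "pool1": 100,
            "conv2": 92,
            "pool2": 46,
            "flatten": 2944,
        }

    def test_conv1_output_matches_input_length(self):
        cfg = NetConfig(arch="cnn")
        assert nets.cnn_layer_lengths(cfg)["conv1"] == cfg.input_len

    def test_inconsistent_padding_arithmetic_rejected(self):
        with pytest.raises(ValueError):
            nets.cnn_layer_lengths(NetConfig(arch="cnn", conv1_len=10))

    def test_replicate_padding_of_constant(self):
        layer = nets.ReplicatePad1d(5)
        x = np.full((200, 3, 1), 7.0, dtype=np.float32)
        out = layer.forward(x)
        assert out.shape == (210, 3, 1)
        assert np.all(out == 7.0)

    def test_replicate_padding_edge_values(self):
        layer = nets.ReplicatePad1d(2)
        x = np.arange(4, dtype=np.float32).reshape(4, 1, 1)
        out = layer.forward(x)[:, 0, 0]
        np.testing.assert_array_equal(out, [0, 0, 0, 1, 2, 3, 3, 3])

    def test_ann_parameter_count(self):
        model = nets.build_ann(NetConfig(arch="ann"))
        assert nets.parameter_count(model) == 25303

    def test_cnn_forward_shapes(self):
        model = nets.build_cnn(NetConfig(arch="cnn", seed=1))
        logits = model.forward(np.random.default_rng(0).normal(size=(4, 200)))
        assert logits.shape == (4, 3)

    def test_zero_weights_give_uniform_softmax(self):
        model = nets.build_ann(NetConfig(arch="ann"))
        for layer in model.layers:
            for k in layer.params:
                layer.params[k] = np.zeros_like(layer.params[k])
        p = nets.softmax(model.forward(np.random.default_rng(0).normal(size=(5, 200))))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-7)

    def test_softmax_sums_to_one(self):
        model = nets.build_cnn(NetConfig(arch="cnn", seed=2))
        p = nets.softmax(model.forward(np.random.default_rng(3).normal(size=(8, 200))))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(lr=0.0)
        with pytest.raises(ValueError):
            NetConfig(patience=0)
        with pytest.raises(ValueError):
            NetConfig(arch="transformer")
        with pytest.raises(ValueError):
            NetConfig(standardization="global")


class TestLayersBackward:
    def _fd_check(self, layer, x, rtol=2e-2):
        rng = np.random.default_rng(0)
        out = layer.forward(x)
        g = rng.normal(size=out.shape).astype(np.float32)
        gx = layer.backward(g)
        eps = 1e-2
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (np.sum(layer.forward(xp) * g) - np.sum(layer.forward(xm) * g)) / (2 * eps)
            if abs(num) > 1e-3:
                assert gx[idx] == pytest.approx(num, rel=rtol)

    def test_conv_backward_finite_difference(self):
        rng = np.random.default_rng(1)
        layer = nets.Conv1d(3, 4, 5, rng)
        x = rng.normal(size=(12, 6, 3)).astype(np.float32)
        self._fd_check(layer, x)

    def test_dense_backward_finite_difference(self):
        rng = np.random.default_rng(2)
        layer = nets.Dense(10, 4, rng)
        x = rng.normal(size=(7, 10)).astype(np.float32)
        self._fd_check(layer, x)

    def test_maxpool_routes_to_argmax(self):
        layer = nets.MaxPool1d(2)
        x = np.array([[[1.0], [3.0], [2.0], [2.0]]], dtype=np.float32).reshape(4, 1, 1)
        out = layer.forward(x)
        np.testing.assert_array_equal(out[:, 0, 0], [3.0, 2.0])
        g = np.ones_like(out)
        gx = layer.backward(g)[:, 0, 0]
        np.testing.assert_array_equal(gx, [0, 1, 1, 0])  # tie -> first index


class TestStandardize:
    def test_none_is_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 200))
        [out], _ = nets.standardize(X, [X], "none")
        np.testing.assert_allclose(out, X, atol=1e-6)

    def test_samplewise_zero_mean_unit_std(self):
        X = np.arange(1, 201, dtype=float)[None, :]
        [out], _ = nets.standardize(X, [X], "samplewise")
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=1e-6)

    def test_featurewise_uses_train_statistics_only(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=(50, 200))
        val = rng.normal(size=(20, 200))
        [tr, va], stats = nets.standardize(train, [train, val], "featurewise")
        mu, sd = train.mean(axis=0), train.std(axis=0)
        np.testing.assert_allclose(stats["mean"], mu, atol=1e-12)
        np.testing.assert_allclose(va, (val - mu) / sd, atol=1e-5)

    def test_featurewise_constant_feature_floored(self):
        train = np.random.default_rng(1).normal(size=(30, 200))
        train[:, 17] = 5.0
        val = np.random.default_rng(2).normal(size=(10, 200))
        val[:, 17] = 5.0
        [tr, va], _ = nets.standardize(train, [train, val], "featurewise")
        assert np.all(tr[:, 17] == 0)
        assert np.all(va[:, 17] == 0)

    def test_featurewise_empty_train_rejected(self):
        with pytest.raises(ValueError):
            nets.standardize(np.empty((0, 200)), [np.empty((0, 200))], "featurewise")


class TestClassWeights:
    def test_paper_pattern_4_4_1(self):
        counts = np.array([1, 1, 4]) * 1000  # proportions 1/6, 1/6, 2/3
        np.testing.assert_allclose(nets.class_weights(counts), [4.0, 4.0, 1.0])

    def test_equal_counts(self):
        np.testing.assert_allclose(nets.class_weights([10, 10, 10]), [1, 1, 1])

    def test_quarter_quarter_half(self):
        np.testing.assert_allclose(nets.class_weights([25, 25, 50]), [2, 2, 1])

    def test_zero_count_rejected_with_class_name(self):
        with pytest.raises(ValueError, match="fibrolipidic"):
            nets.class_weights([10, 0, 10])


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert nets.weighted_cross_entropy([1, 0, 0], [1, 0, 0], [1, 1, 1]) == 0.0

    def test_half_probability(self):
        loss = nets.weighted_cross_entropy([1, 0, 0], [0.5, 0.25, 0.25], [1, 1, 1])
        assert loss == pytest.approx(-np.log(0.5), abs=1e-10)

    def test_linear_in_weight(self):
        l1 = nets.weighted_cross_entropy([1, 0, 0], [0.5, 0.25, 0.25], [1, 1, 1])
        l2 = nets.weighted_cross_entropy([1, 0, 0], [0.5, 0.25, 0.25], [2, 1, 1])
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_zero_probability_clamped(self):
        loss = nets.weighted_cross_entropy([1, 0, 0], [0.0, 0.5, 0.5], [1, 1, 1])
        assert loss == pytest.approx(-np.log(1e-12))

    def test_batch_mean_formula_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=16)
        y = rng.integers(0, 3, 16)
        w = np.array([4.0, 4.0, 1.0])
        onehot = np.eye(3)[y]
        expected = np.mean([w[y[i]] * -np.log(p[i, y[i]]) for i in range(16)])
        assert nets.weighted_cross_entropy(onehot, p, w) == pytest.approx(expected, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(5, 3))
        y = rng.integers(0, 3, 5)
        w = np.array([4.0, 4.0, 1.0])
        _, g = nets._loss_and_grad(logits, y, w)
        eps = 1e-6
        for i in range(5):
            for j in range(3):
                lp, lm = logits.copy(), logits.copy()
                lp[i, j] += eps
                lm[i, j] -= eps
                num = (
                    nets._loss_and_grad(lp, y, w)[0] - nets._loss_and_grad(lm, y, w)[0]
                ) / (2 * eps)
                assert g[i, j] == pytest.approx(num, abs=1e-5)


class TestEarlyStopping:
    def test_hand_traced_patience(self):
        stopper = nets.EarlyStopping(patience=5, min_rel_improvement=1e-4)
        losses = [1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9]
        stops = [stopper.update(v) for v in losses]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 2

    def test_monotone_improvement_never_stops(self):
        stopper = nets.EarlyStopping(patience=5, min_rel_improvement=1e-4)
        for i in range(100):
            assert not stopper.update(1.0 * 0.99**i)
        assert stopper.best_epoch == 100

    def test_sub_threshold_improvement_counts_as_stall(self):
        stopper = nets.EarlyStopping(patience=2, min_rel_improvement=1e-4)
        assert not stopper.update(1.0)
        assert not stopper.update(1.0 - 1e-6)  # below 0.01% relative
        assert stopper.update(1.0 - 2e-6)
        assert stopper.best_epoch == 3  # still tracks the minimum


class TestTraining:
    def _tiny_data(self, n=300):
        rng = np.random.default_rng(0)
        X, y, _ = make_aline_dataset(n // 3, rng)
        return X, y

    def test_determinism(self):
        X, y = self._tiny_data()
        cfg = NetConfig(arch="ann", max_epochs=3, seed=5, batch_size=64)
        t1 = nets.train(nets.build_ann(cfg), X[:200], y[:200], X[200:], y[200:], cfg)
        t2 = nets.train(nets.build_ann(cfg), X[:200], y[:200], X[200:], y[200:], cfg)
        for l1, l2 in zip(t1.model.layers, t2.model.layers):
            for k in l1.params:
                np.testing.assert_array_equal(l1.params[k], l2.params[k])
        assert t1.history == t2.history

    def test_max_epoch_cap(self):
        X, y = self._tiny_data(90)
        cfg = NetConfig(arch="ann", max_epochs=4, seed=0, batch_size=32)
        trained = nets.train(nets.build_ann(cfg), X[:60], y[:60], X[60:], y[60:], cfg)
        assert len(trained.history["val_loss"]) <= 4

    def test_best_epoch_has_min_val_loss(self):
        X, y = self._tiny_data()
        cfg = NetConfig(arch="ann", max_epochs=6, seed=1, batch_size=64)
        trained = nets.train(nets.build_ann(cfg), X[:200], y[:200], X[200:], y[200:], cfg)
        vals = trained.history["val_loss"]
        assert trained.best_epoch == int(np.argmin(vals)) + 1

    def test_class_weight_effect_no_collapse(self):
        # 10:10:80 imbalance; weighted training keeps per-class recall close
        rng = np.random.default_rng(9)
        X, y, _ = make_aline_dataset(700, rng)
        keep = []
        quota = {0: 150, 1: 150, 2: 1200}
        for i, lab in enumerate(y):
            if quota[int(lab)] > 0:
                quota[int(lab)] -= 1
                keep.append(i)
        X, y = X[keep], y[keep]
        cut = int(0.8 * len(y))
        cfg = NetConfig(arch="ann", max_epochs=12, seed=2, batch_size=128)
        trained = nets.train(nets.build_ann(cfg), X[:cut], y[:cut], X[cut:], y[cut:], cfg)
        pred = nets.predict(trained, X[cut:]).argmax(axis=1)
        recalls = [
            (pred[y[cut:] == c] == c).mean() for c in range(3) if (y[cut:] == c).sum()
        ]
        assert max(recalls) - min(recalls) <= 0.15


class TestPredict:
    def test_probabilities_sum_to_one(self, trained_ann, aline_data):
        X, _, _ = aline_data
        p = nets.predict(trained_ann, X[:50])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_per_example(self, trained_ann, aline_data):
        X, _, _ = aline_data
        batch = nets.predict(trained_ann, X[:20])
        singles = np.vstack([nets.predict(trained_ann, X[i]) for i in range(20)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_wrong_length_rejected(self, trained_ann):
        with pytest.raises(ValueError, match="length"):
            nets.predict(trained_ann, np.zeros((3, 100)))

    def test_cnn_heldout_accuracy(self, trained_cnn, aline_data):
        X, y, _ = aline_data
        cut = int(0.85 * len(y))
        p = nets.predict(trained_cnn, X[cut:])
        assert (p.argmax(axis=1) == y[cut:]).mean() >= 0.9

    def test_translation_tolerance_of_cnn(self, trained_cnn):
        # shifting the calcium border +/-10 px rarely changes the call;
        # probes are built directly for control over the border position
        n = 500
        from octaline import sim as sim_mod
        from scipy import ndimage as ndi

        params = sim_mod.ProfileParams()
        k = np.exp(-(np.arange(-3, 4) ** 2) / 2.0)
        k /= k.sum()
        preds = {}
        for cap in (20, 30, 40):
            probes = []
            prng = np.random.default_rng(77)  # same speckle across caps
            for _ in range(n):
                prof = sim_mod.generate_aline_profile(
                    sim_mod.FIBROCALCIFIC, 200, params,
                    cap_thickness_px=cap, calcium_thickness_px=100,
                )
                noisy = sim_mod.apply_speckle(prof, 8.0, prng)
                probes.append(ndi.convolve1d(np.log1p(noisy), k, mode="nearest"))
            preds[cap] = nets.predict(trained_cnn, np.asarray(probes)).argmax(axis=1)
        changed = (preds[20] != preds[30]).mean() + (preds[40] != preds[30]).mean()
        assert changed / 2 <= 0.10
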