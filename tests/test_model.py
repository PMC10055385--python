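import numpy as np
import pytest

from tpmrisk import model
from tpmrisk import vocab_tpm as vt
from tpmrisk.errors import ConstructionError, InferenceError, TrainingError
from tpmrisk.evaluate import roc_auc

TOY_SPEC = dict(
    conv1_filters=4,
    conv2_filters=2,
    conv_kernel_weeks=5,
    dense_units=8,
    dropout_rate=0.3,
    epochs=2,
    batch_size=16,
)


def _toy_data(n=40, rows=6, weeks=24, signal=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(np.int64)
    X = rng.random((n, rows, weeks)).astype(np.float32) * 0.2
    X[y == 1, 0, :] += signal
    aux = rng.random((n, 2)).astype(np.float32)
    return np.clip(X, 0, 1), aux, y


class TestBuildModel:
    def test_default_architecture_introspection(self):
        net = model.build_model(model.ModelSpec(), (1928, 131))
        assert net.n_hidden_layers == 8
        assert net.hidden_layers == model.HIDDEN_LAYERS
        assert net.dense_units == 128
        assert net.dropout_rate == 0.3

    def test_zero_dropout_valid_and_identity_at_inference(self):
        spec = model.ModelSpec(**{**TOY_SPEC, "dropout_rate": 0.0})
        net = model.build_model(spec, (6, 24))
        X, aux, y = _toy_data()
        p1 = model.predict(net, (X, aux))
        p2 = model.predict(net, (X, aux))
        assert np.array_equal(p1, p2)

    def test_toy_shape_forward(self):
        spec = model.ModelSpec(**{**TOY_SPEC, "conv_kernel_weeks": 3})
        net = model.build_model(spec, (4, 8))
        X = np.random.default_rng(0).random((5, 4, 8)).astype(np.float32)
        aux = np.zeros((5, 2), dtype=np.float32)
        probs = model.predict(net, (X, aux))
        assert probs.shape == (5,)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_shape_too_small_names_layer(self):
        with pytest.raises(ConstructionError, match="average_pooling2d"):
            model.build_model(model.ModelSpec(**TOY_SPEC), (1, 8))
        with pytest.raises(ConstructionError, match="max_pooling2d"):
            model.build_model(model.ModelSpec(**TOY_SPEC), (2, 4))

    def test_invalid_spec(self):
        with pytest.raises(ConstructionError):
            model.ModelSpec(dropout_rate=1.0)
        with pytest.raises(ConstructionError):
            model.ModelSpec(epochs=0)


class TestTrain:
    def test_single_class_raises(self):
        net = model.build_model(model.ModelSpec(**TOY_SPEC), (6, 24))
        X, aux, y = _toy_data()
        with pytest.raises(TrainingError):
            model.train(net, (X, aux), labels=np.zeros_like(y))

    def test_deterministic_history(self):
        X, aux, y = _toy_data(signal=0.3)
        hists, preds = [], []
        for _ in range(2):
            spec = model.ModelSpec(**TOY_SPEC, seed=7)
            net = model.build_model(spec, (6, 24))
            model.train(net, (X, aux), labels=y, spec=spec)
            hists.append(net.history)
            preds.append(model.predict(net, (X, aux)))
        assert hists[0] == hists[1]
        assert np.array_equal(preds[0], preds[1])

    def test_history_records_every_epoch(self):
        X, aux, y = _toy_data()
        spec = model.ModelSpec(**{**TOY_SPEC, "epochs": 3})
        net = model.build_model(spec, (6, 24))
        model.train(net, (X, aux), labels=y, spec=spec)
        assert [h["epoch"] for h in net.history] == [0, 1, 2]
        assert all(np.isfinite(h["loss"]) for h in net.history)

    def test_separable_signal_training_auroc(self, sim_maps):
        # planted multiplier-5 cohort: training AUROC should exceed 0.9
        _, maps = sim_maps
        stats = vt.fit_normalization(maps)
        X, aux, y, _ = vt.stack_maps(vt.normalize_maps(maps, stats))
        spec = model.ModelSpec(epochs=12, learning_rate=3e-3, seed=1)
        net = model.build_model(spec, X.shape[1:])
        model.train(net, (X, aux), labels=y, spec=spec)
        scores = model.predict(net, (X, aux))
        assert roc_auc(scores, y, ci=None).value > 0.9

    def test_permuted_labels_near_chance(self):
        # null signal: mean holdout AUROC over 10 seeds stays near 0.5
        aucs = []
        for seed in range(10):
            X, aux, y = _toy_data(n=120, signal=0.0, seed=seed)
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            spec = model.ModelSpec(**TOY_SPEC, seed=seed)
            net = model.build_model(spec, (6, 24))
            model.train(net, (X[:80], aux[:80]), labels=yp[:80], spec=spec)
            scores = model.predict(net, (X[80:], aux[80:]))
            aucs.append(roc_auc(scores, yp[80:], ci=None).value)
        assert 0.4 <= float(np.mean(aucs)) <= 0.6


class TestPredict:
    def test_probabilities_in_unit_interval(self):
        net = model.build_model(model.ModelSpec(**TOY_SPEC), (6, 24))
        X, aux, _ = _toy_data(n=30)
        p = model.predict(net, (X, aux))
        assert ((p >= 0) & (p <= 1)).all()

    def test_same_input_same_output(self):
        net = model.build_model(model.ModelSpec(**TOY_SPEC), (6, 24))
        X, aux, _ = _toy_data(n=10)
        assert np.array_equal(model.predict(net, (X, aux)), model.predict(net, (X, aux)))

    def test_shape_mismatch(self):
        net = model.build_model(model.ModelSpec(**TOY_SPEC), (6, 24))
        with pytest.raises(InferenceError):
            model.predict(net, (np.zeros((3, 5, 24), dtype=np.float32), np.zeros((3, 2))))

    def test_zero_map_scores_below_signal_map(self):
        X, aux, y = _toy_data(n=200, signal=0.6, seed=3)
        spec = model.ModelSpec(**{**TOY_SPEC, "epochs": 15}, learning_rate=3e-3, seed=3)
        net = model.build_model(spec, (6, 24))
        model.train(net, (X, aux), labels=y, spec=spec)
        zero = np.zeros((1, 6, 24), dtype=np.float32)
        hot = np.zeros((1, 6, 24), dtype=np.float32)
        hot[0, 0, :] = 0.8
        a = np.full((1, 2), 0.5, dtype=np.float32)
        assert model.predict(net, (zero, a))[0] < model.predict(net, (hot, a))[0]

    def test_aux_inputs_matter(self):
        # label driven by age alone: zeroing aux must change predictions
        rng = np.random.default_rng(5)
        n = 200
        X = (rng.random((n, 6, 24)) * 0.1).astype(np.float32)
        age = rng.random(n).astype(np.float32)
        aux = np.stack([age, rng.integers(0, 2, n).astype(np.float32)], axis=1)
        y = (age > 0.5).astype(np.int64)
        spec = model.ModelSpec(**{**TOY_SPEC, "epochs": 20}, learning_rate=3e-3, seed=5)
        net = model.build_model(spec, (6, 24))
        model.train(net, (X, aux), labels=y, spec=spec)
        p_real = model.predict(net, (X, aux))
        p_zero = model.predict(net, (X, np.zeros_like(aux)))
        assert roc_auc(p_real, y, ci=None).value > 0.7
        assert not np.allclose(p_real, p_zero)


def test_maps_api_roundtrip(sim_maps):
    # list-of-maps API and (X, aux) API agree
    _, maps = sim_maps
    stats = vt.fit_normalization(maps)
    nm = vt.normalize_maps(maps[:25] + maps[-25:], stats)
    X, aux, y, _ = vt.stack_maps(nm)
    spec = model.ModelSpec(epochs=1, seed=0)
    net = model.build_model(spec, X.shape[1:])
    model.train(net, nm, spec=spec)
    p1 = model.predict(net, nm)
    p2 = model.predict(net, (X, aux))
    assert np.allclose(p1, p2)


def test_gradients_match_finite_differences():
    # conv leak large enough that float32 finite differences resolve it
    spec = model.ModelSpec(
        conv1_filters=3, conv2_filters=2, conv_kernel_weeks=5, dense_units=4,
        dropout_rate=0.0, conv_leaky_alpha=0.3, epochs=1, batch_size=4, seed=0,
    )
    net = model.build_model(spec, (4, 12))
    rng = np.random.default_rng(1)
    X = rng.random((6, 4, 12)).astype(np.float32)
    aux = rng.random((6, 2)).astype(np.float32)
    y = np.array([0, 1, 0, 1, 1, 0], dtype=np.float32)

    def loss():
        logit, _ = net._forward(X, aux, train=False)
        return float(np.mean(np.logaddexp(0, logit) - y * logit))

    logit, cache = net._forward(X, aux, train=True, rng=np.random.default_rng(0))
    prob = 1 / (1 + np.exp(-logit))
    net._backward(((prob - y) / len(y)).astype(np.float32), cache)
    grads = [g.copy() for g in net._gradients()]
    eps = 1e-3
    for p, g in zip(model._param_arrays(net), grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 5)):
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + eps
            lp = loss()
            p[idx] = old - eps
            lm = loss()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            # absolute floor covers float32 noise on near-zero gradients
            assert abs(num - g[idx]) <= 0.05 * max(5e-3, abs(num) + abs(g[idx]))
            it.iternext()
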