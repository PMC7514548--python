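"""Trainable networks: gradients, presets, determinism, separable training."""

import numpy as np
import pytest

from capscore.errors import DegenerateLabelError, NotTrainedError
from capscore.evaluation import auc
from capscore.networks.layers import SoftmaxCrossEntropy
from capscore.networks.models import (
    NetworkSpec, TrainingConfig, build_network, cnn_spec, gru_spec, load_model,
    lstm_spec, predict_phases, resolve_spec, save_model, train_classifier,
)
from capscore.networks.estimators import (
    CNNPhaseClassifier, GRUPhaseClassifier, LSTMPhaseClassifier,
)


def finite_difference_check(spec, x, y, rng, n_probes=8, eps=1e-6):
    """Max |analytic - central-difference| gradient error over random entries."""
    model = build_network(spec, seed=0)
    logits = model.forward(x, training=True)
    _, dlogits = SoftmaxCrossEntropy.loss_and_grad(logits, y)
    model.zero_grads()
    model.backward(dlogits)
    worst = 0.0
    for p, g in zip(model.params, model.grads):
        for _ in range(n_probes):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            keep = p[idx]
            p[idx] = keep + eps
            lp, _ = SoftmaxCrossEntropy.loss_and_grad(
                model.forward(x, training=True), y)
            p[idx] = keep - eps
            lm, _ = SoftmaxCrossEntropy.loss_and_grad(
                model.forward(x, training=True), y)
            p[idx] = keep
            worst = max(worst, abs((lp - lm) / (2 * eps) - g[idx]))
    return worst


class TestGradients:
    def test_lstm_backprop_matches_finite_differences(self, rng):
        x = rng.standard_normal((3, 4, 100))
        y = rng.integers(0, 2, (3, 4))
        assert finite_difference_check(lstm_spec(6, 5), x, y, rng) < 1e-6

    def test_gru_backprop_matches_finite_differences(self, rng):
        x = rng.standard_normal((3, 4, 100))
        y = rng.integers(0, 2, (3, 4))
        assert finite_difference_check(gru_spec(6, 5), x, y, rng) < 1e-6

    def test_cnn_backprop_matches_finite_differences(self, rng):
        x = rng.standard_normal((6, 100, 1))
        y = rng.integers(0, 2, 6)
        assert finite_difference_check(cnn_spec((4, 8)), x, y, rng) < 1e-6


class TestPresets:
    def test_lstm_preset_structure(self):
        spec = resolve_spec("lstm_table1")
        kinds = [d["kind"] for d in spec.layers]
        assert kinds == ["input", "lstm", "dense", "dense", "softmax"]
        assert spec.layers[1]["units"] == 400
        assert spec.layers[2] == {"kind": "dense", "units": 30,
                                  "activation": "selu"}

    def test_gru_preset_structure(self):
        spec = resolve_spec("gru_table1")
        assert spec.layers[1] == {"kind": "gru", "units": 200}
        assert spec.layers[2]["units"] == 20

    def test_cnn_preset_structure(self):
        spec = resolve_spec("cnn_table1")
        kinds = [d["kind"] for d in spec.layers]
        assert kinds == ["input", "conv", "batchnorm", "relu", "maxpool",
                         "conv", "batchnorm", "relu", "globalavgpool",
                         "dense", "softmax"]
        assert spec.layers[1]["filters"] == 64
        assert spec.layers[5]["filters"] == 128
        assert spec.layers[4]["size"] == 3

    def test_parameter_count_reported(self):
        model = build_network(lstm_spec(8, 4))
        # 4 gates: (100 + 8 + 1) * 8 * 4, dense 8*4+4, head 4*2+2
        assert model.n_parameters == 4 * (100 * 8 + 8 * 8 + 8) + (8 * 4 + 4) + (4 * 2 + 2)

    def test_invalid_head_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec("bad", (
                {"kind": "input", "units": 100},
                {"kind": "dense", "units": 3, "activation": "linear"},
                {"kind": "softmax"},
            ))


class TestTraining:
    def _small_config(self, **kw):
        base = dict(n_passes=8, batch_size=64, context_length=20,
                    learning_rate=3e-3, seed=3)
        base.update(kw)
        return TrainingConfig(**base)

    @pytest.mark.parametrize("spec_factory", [
        lambda: lstm_spec(16, 8), lambda: gru_spec(16, 8),
        lambda: cnn_spec((8, 16)),
    ], ids=["lstm", "gru", "cnn"])
    def test_separable_data_learned(self, separable_epochs, spec_factory):
        x, y, rid = separable_epochs
        model = build_network(spec_factory(), seed=1)
        train_classifier(model, x, y, self._small_config(n_passes=30),
                         recording_ids=rid)
        assert model.training_log_[-1] < model.training_log_[0]
        scores = predict_phases(model, x)
        assert scores.proba.shape == (x.shape[0],)
        assert auc(scores.proba, y) > 0.95

    def test_loss_decreases_early(self, separable_epochs):
        x, y, rid = separable_epochs
        model = build_network(lstm_spec(16, 8), seed=1)
        train_classifier(model, x, y, self._small_config(), recording_ids=rid)
        log = model.training_log_
        assert all(b < a for a, b in zip(log[:3], log[1:4]))

    def test_single_class_labels_rejected(self, rng):
        model = build_network(lstm_spec(4, 4))
        with pytest.raises(DegenerateLabelError):
            train_classifier(model, rng.standard_normal((50, 100)),
                             np.zeros(50), self._small_config())

    def test_training_is_seed_deterministic(self, separable_epochs):
        x, y, rid = separable_epochs
        weights = []
        for _ in range(2):
            model = build_network(lstm_spec(8, 4), seed=9)
            train_classifier(model, x, y, self._small_config(n_passes=3),
                             recording_ids=rid)
            weights.append([p.copy() for p in model.params])
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_untrained_model_rejected(self, rng):
        with pytest.raises(NotTrainedError):
            predict_phases(build_network(lstm_spec(4, 4)),
                           rng.standard_normal((5, 100)))

    def test_probabilities_well_formed(self, separable_epochs):
        x, y, rid = separable_epochs
        model = build_network(cnn_spec((8, 16)), seed=1)
        train_classifier(model, x, y, self._small_config(), recording_ids=rid)
        scores = predict_phases(model, x)
        assert np.all((scores.proba >= 0) & (scores.proba <= 1))
        assert np.array_equal(scores.labels, (scores.proba >= 0.5))

    def test_samples_sequence_mode_trains(self, separable_epochs):
        # recurrence across the 100 samples within one epoch, seq-to-one
        x, y, rid = separable_epochs
        model = build_network(lstm_spec(8, 4), seed=2, sequence_mode="samples")
        train_classifier(model, x[:200], y[:200],
                         self._small_config(n_passes=2))
        assert predict_phases(model, x[:50]).proba.shape == (50,)

    def test_checkpoint_round_trip(self, separable_epochs, tmp_path):
        x, y, rid = separable_epochs
        cfg = self._small_config(n_passes=2)
        model = build_network(cnn_spec((8, 16)), seed=5)
        train_classifier(model, x, y, cfg, recording_ids=rid)
        path = tmp_path / "model.npz"
        save_model(model, path, config=cfg)
        restored, cfg2 = load_model(path)
        np.testing.assert_array_equal(predict_phases(restored, x[:40]).proba,
                                      predict_phases(model, x[:40]).proba)
        assert cfg2 == cfg


class TestEstimators:
    def test_sklearn_contract(self, separable_epochs):
        x, y, rid = separable_epochs
        est = LSTMPhaseClassifier(cells=8, dense_units=4, n_passes=3,
                                  context_length=20, seed=0)
        params = est.get_params()
        assert params["cells"] == 8
        est.set_params(n_passes=2)
        est.fit(x, y, recording_ids=rid)
        assert hasattr(est, "model_") and est.n_parameters_ > 0
        proba = est.predict_proba(x[:30])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert set(np.unique(est.predict(x[:30]))) <= {0, 1}

    def test_clone_compatible(self, separable_epochs):
        from sklearn.base import clone

        est = GRUPhaseClassifier(cells=6, n_passes=2, context_length=10)
        clone(est)  # raises if the constructor breaks the contract

    def test_estimator_auc_on_separable_fixture(self, separable_epochs):
        x, y, rid = separable_epochs
        est = CNNPhaseClassifier(n_passes=10, seed=4)
        est.fit(x, y, recording_ids=rid)
        assert auc(est.decision_function(x), y) > 0.95
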