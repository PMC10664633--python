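import numpy as np
import pytest

from conftest import make_table
from ddafuse.classifier import (
    MLPModel,
    NetworkConfig,
    _bce,
    build_model,
    history_to_csv,
    predict_scores,
    train,
)
from ddafuse.core_data import ParameterError, ValidationError
from ddafuse.similarity import DimensionError

FAST = dict(hidden_layers=2, units_per_layer=32, epochs=20, batch_size=32, seed=0)


class TestBuildModel:
    def test_default_architecture_shapes(self):
        model = build_model(10, NetworkConfig())
        assert [w.shape for w in model.W] == [(10, 300)] + [(300, 300)] * 4 + [(300, 1)]

    def test_published_defaults(self):
        cfg = NetworkConfig()
        assert (cfg.hidden_layers, cfg.units_per_layer) == (5, 300)
        assert (cfg.dropout_rate, cfg.batch_size, cfg.epochs, cfg.optimizer) == (
            0.3, 64, 200, "nadam",
        )

    def test_zero_hidden_layers_is_logistic_regression(self):
        model = build_model(4, NetworkConfig(hidden_layers=0))
        assert [w.shape for w in model.W] == [(4, 1)]

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            NetworkConfig(dropout_rate=1.5)
        with pytest.raises(ParameterError):
            NetworkConfig(optimizer="adagrad")

    @pytest.mark.parametrize("arch", ["dense", "conv1d"])
    def test_gradients_match_finite_differences(self, arch):
        cfg = NetworkConfig(
            hidden_layers=2, units_per_layer=7, dropout_rate=0.0,
            architecture=arch, conv_filters=3, seed=0,
        )
        model = MLPModel(9, cfg)
        rng = np.random.default_rng(1)
        X = rng.random((6, 9))
        y = rng.integers(0, 2, 6).astype(float)
        _, caches = model._forward(X)
        gW, gb, gK, gcb = model._backward_full(X, y, caches)

        def loss():
            p, _ = model._forward(X)
            return _bce(y, p)

        eps = 1e-6
        checks = [(model.W[0], gW[0]), (model.b[1], gb[1])]
        if gK is not None:
            checks.append((model.conv_K, gK))
        for param, grad in checks:
            idx = tuple(0 for _ in param.shape)
            param[idx] += eps
            up = loss()
            param[idx] -= 2 * eps
            down = loss()
            param[idx] += eps
            assert abs((up - down) / (2 * eps) - grad[idx]) < 1e-6


class TestTrain:
    def test_separable_blobs_reach_high_accuracy(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 50})
        model = train(build_model(8, cfg), blob_table, cfg)
        assert model.history[-1]["train_acc"] > 0.95

    def test_loss_decreases_on_average(self, blob_table):
        cfg = NetworkConfig(**FAST)
        model = train(build_model(8, cfg), blob_table, cfg)
        losses = [h["train_loss"] for h in model.history]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_zero_epochs_returns_untrained_model(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 0})
        model = train(build_model(8, cfg), blob_table, cfg)
        assert model.history == []
        assert not model.fitted

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.random((20, 4)), np.ones(20, dtype=int))
        cfg = NetworkConfig(**FAST)
        with pytest.raises(ValidationError):
            train(build_model(4, cfg), table, cfg)

    def test_validation_history_recorded(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 3})
        model = train(build_model(8, cfg), blob_table, cfg, validation_fraction=0.3)
        assert {"val_loss", "val_acc"} <= set(model.history[0])

    def test_seeded_training_reproducible(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 5})
        m1 = train(build_model(8, cfg), blob_table, cfg)
        m2 = train(build_model(8, cfg), blob_table, cfg)
        assert m1.history == m2.history
        assert all(np.array_equal(a, b) for a, b in zip(m1.W, m2.W))

    def test_conv1d_variant_trains(self, blob_table):
        cfg = NetworkConfig(
            hidden_layers=1, units_per_layer=16, epochs=10, batch_size=32,
            architecture="conv1d", conv_filters=4, seed=0,
        )
        model = train(build_model(8, cfg), blob_table, cfg)
        losses = [h["train_loss"] for h in model.history]
        assert losses[-1] < losses[0]


class TestPredict:
    def test_scores_in_unit_interval(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 5})
        model = train(build_model(8, cfg), blob_table, cfg)
        scores = predict_scores(model, blob_table.features)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_duplicate_rows_get_identical_scores(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 5})
        model = train(build_model(8, cfg), blob_table, cfg)
        row = blob_table.features[0]
        scores = predict_scores(model, np.vstack([row, row]))
        assert scores[0] == scores[1]

    def test_classes_separated_after_training(self, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 30})
        model = train(build_model(8, cfg), blob_table, cfg)
        scores = predict_scores(model, blob_table.features)
        pos = scores[blob_table.labels == 1].mean()
        neg = scores[blob_table.labels == 0].mean()
        assert pos > neg

    def test_width_mismatch_rejected(self, blob_table):
        model = build_model(8, NetworkConfig(**FAST))
        with pytest.raises(DimensionError):
            predict_scores(model, np.ones((2, 5)))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 3})
        model = train(build_model(8, cfg), blob_table, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = MLPModel.load(path)
        assert np.array_equal(
            predict_scores(model, blob_table.features),
            predict_scores(loaded, blob_table.features),
        )

    def test_history_export(self, tmp_path, blob_table):
        cfg = NetworkConfig(**{**FAST, "epochs": 3})
        model = train(build_model(8, cfg), blob_table, cfg)
        history_to_csv(model, tmp_path / "history.csv")
        header = (tmp_path / "history.csv").read_text().splitlines()[0]
        assert header.startswith("epoch,train_loss,train_acc")
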