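"""Weighted-BCE classifier: loss, weights, grid search, CV, prediction."""

import numpy as np
import pytest
from sklearn.metrics import log_loss

from offtarget_bias.model import (
    ClassifierArtifact,
    HyperGrid,
    TrainConfig,
    class_weights_from_counts,
    cross_validate,
    grid_search,
    predict,
    train_classifier,
    weighted_bce,
)

FAST = TrainConfig(hidden_units=32, batch_size=64, max_epochs=80)


def _one_bit_dataset(rng, n=400, d=64, noise=0.01):
    """Labels equal one (class-balanced) fingerprint bit up to a small flip rate."""
    x = (rng.random((n, d)) < 0.3).astype(np.float32)
    x[:, 0] = rng.random(n) < 0.5
    y = x[:, 0].astype(int).copy()
    n_flips = int(round(noise * n))
    if n_flips:
        flips = rng.choice(n, n_flips, replace=False)
        y[flips] = 1 - y[flips]
    return x, y


class TestWeightedBCE:
    def test_unit_weights_equal_unweighted_bce(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.uniform(0.01, 0.99, 200)
        assert weighted_bce(y, p, (1.0, 1.0)) == pytest.approx(
            log_loss(y, p, labels=[0, 1]), abs=1e-10
        )

    def test_perfect_prediction_loss_vanishes(self):
        assert weighted_bce(np.array([1.0]), np.array([1 - 1e-9]), (3.0, 7.0)) < 1e-5

    def test_hand_computed_example(self):
        # -(2*log 0.5 + 1*log 0.5)/2 with (w_neg, w_pos) = (2, 1)
        loss = weighted_bce(np.array([1, 0]), np.array([0.5, 0.5]), (2.0, 1.0))
        assert loss == pytest.approx(1.5 * np.log(2))

    def test_minority_errors_cost_more(self, rng):
        y = np.array([1, 0])
        p = np.array([0.1, 0.9])  # both wrong
        w = class_weights_from_counts(n_neg=900, n_pos=100)
        base = weighted_bce(y, p, (1.0, 1.0))
        assert weighted_bce(np.array([1]), np.array([0.1]), w) > base

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_bce(np.array([1, 0]), np.array([0.5]), (1, 1))


class TestClassWeights:
    @pytest.mark.parametrize(
        "n_neg, n_pos, expected",
        [
            (100, 100, (1.0, 1.0)),
            (951, 3797, (2.4963196635, 0.6252304451)),
            (1, 999, (500.0, 0.5005005005)),
        ],
    )
    def test_balanced_formula(self, n_neg, n_pos, expected):
        w = class_weights_from_counts(n_neg, n_pos)
        assert w == pytest.approx(expected)

    def test_zero_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            class_weights_from_counts(0, 100)


class TestTraining:
    def test_separable_dataset_learned(self, rng):
        x, y = _one_bit_dataset(rng)
        artifact = train_classifier(x, y, FAST)
        _, calls = predict(artifact, x)
        assert (calls == y).mean() > 0.97

    def test_early_stopping_respects_patience(self, rng):
        x, y = _one_bit_dataset(rng, n=200)
        cfg = TrainConfig(hidden_units=16, batch_size=64, max_epochs=500, stop_patience=10)
        artifact = train_classifier(x, y, cfg)
        losses = [h["loss"] for h in artifact.training_history]
        if len(losses) < cfg.max_epochs:  # stopped early
            best = min(losses)
            assert best not in losses[-cfg.stop_patience :] or np.isclose(
                min(losses[-cfg.stop_patience :]), best
            )
            assert min(losses[: -cfg.stop_patience]) <= min(losses[-cfg.stop_patience :]) + 1e-6

    def test_lr_reduced_on_plateau(self, rng):
        x, y = _one_bit_dataset(rng, n=200)
        cfg = TrainConfig(hidden_units=16, batch_size=64, max_epochs=300, lr_patience=5, stop_patience=40)
        artifact = train_classifier(x, y, cfg)
        lrs = {h["lr"] for h in artifact.training_history}
        assert len(lrs) > 1, "learning rate should have been cut at least once"
        assert min(lrs) >= cfg.min_lr

    def test_deterministic_given_seed(self, rng):
        x, y = _one_bit_dataset(rng, n=150)
        p1, _ = predict(train_classifier(x, y, FAST), x)
        p2, _ = predict(train_classifier(x, y, FAST), x)
        assert np.array_equal(p1, p2)

    def test_single_class_training_rejected(self, rng):
        x = (rng.random((50, 16)) < 0.3).astype(np.float32)
        with pytest.raises(ValueError):
            train_classifier(x, np.ones(50), FAST)


class TestPredict:
    def test_threshold_boundary_is_active(self, rng):
        x, y = _one_bit_dataset(rng, n=150)
        artifact = train_classifier(x, y, FAST)
        proba, calls = predict(artifact, x)
        assert np.array_equal(calls, (proba >= 0.5).astype(int))

    def test_dimension_mismatch(self, rng):
        x, y = _one_bit_dataset(rng, n=100, d=32)
        artifact = train_classifier(x, y, FAST)
        with pytest.raises(ValueError):
            predict(artifact, np.zeros((5, 64)))

    def test_save_load_roundtrip(self, rng, tmp_path):
        x, y = _one_bit_dataset(rng, n=100)
        artifact = train_classifier(x, y, FAST)
        artifact.save(tmp_path / "model")
        loaded = ClassifierArtifact.load(tmp_path / "model")
        assert np.array_equal(loaded.predict_proba(x), artifact.predict_proba(x))
        assert loaded.config == artifact.config


class TestGridSearch:
    def test_default_grid_cardinality(self):
        grid = HyperGrid()
        assert len(grid) == 288
        assert len(grid.expand()) == 288

    def test_single_point_grid_returns_that_config(self, rng):
        x, y = _one_bit_dataset(rng, n=200)
        grid = HyperGrid(hidden_units=(16,), dropout_input=(0.0,), dropout_hidden=(0.2,), batch_size=(64,))
        best, rows = grid_search((x, y), grid, seed=0, base_config=FAST)
        assert best.config.hidden_units == 16
        assert len(rows) == 1

    def test_selects_by_validation_mcc(self, rng):
        # labels equal one fingerprint bit exactly: the grid's best model
        # must recover the rule almost perfectly on the validation split
        x, y = _one_bit_dataset(rng, n=300, noise=0.0)
        grid = HyperGrid(hidden_units=(8, 32), dropout_input=(0.0,), dropout_hidden=(0.2,), batch_size=(64,))
        best, rows = grid_search((x, y), grid, seed=1, base_config=FAST)
        assert rows["mcc"].max() >= 0.95
        assert best.selection_metrics.mcc == pytest.approx(rows["mcc"].max())

    def test_single_class_dataset_rejected_before_training(self, rng):
        x = (rng.random((60, 16)) < 0.3).astype(np.float32)
        with pytest.raises(ValueError):
            grid_search((x, np.zeros(60, dtype=int)), HyperGrid(), seed=0)


class TestCrossValidate:
    def test_reports_and_summary_shape(self, rng):
        x, y = _one_bit_dataset(rng, n=100)
        reports, summary = cross_validate(x, y, FAST, k=5, seed=0)
        assert len(reports) == 5
        assert set(summary["metric"]) == {"balanced_accuracy", "accuracy", "recall", "f_measure", "mcc"}

    def test_separable_near_perfect(self, rng):
        x, y = _one_bit_dataset(rng, n=300)
        _, summary = cross_validate(x, y, FAST, k=5, seed=0)
        ba = summary.set_index("metric").loc["balanced_accuracy"]
        assert ba["mean"] >= 0.95 and ba["sd"] < 0.1

    def test_invalid_k(self, rng):
        x, y = _one_bit_dataset(rng, n=100)
        with pytest.raises(ValueError):
            cross_validate(x, y, FAST, k=1)
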