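"""MLP training backend: convergence, determinism, evaluation, grid search."""

from __future__ import annotations

import numpy as np
import pytest

from luxuvi.dataset import InputConfig, TrainingSet, extract, split
from luxuvi.model import (
    GridResult,
    MLPConfig,
    MLPWeights,
    evaluate_mae,
    grid_search,
    predict,
    train,
)


def _toy_set(x: np.ndarray, y: np.ndarray, val_frac: float = 0.2, seed: int = 0) -> TrainingSet:
    n, d = x.shape
    cfg = InputConfig(use_zenith=(d == 2), use_month=False)
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n) < val_frac, "val", "train").astype(object)
    return TrainingSet(
        features=x,
        targets=y,
        config=cfg,
        normalization=tuple((0.0, 1.0) for _ in range(d)),
        months=np.ones(n, dtype=int),
        split_labels=labels,
    )


class TestTrain:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(0)
        x = rng.random((1000, 1))
        ts = _toy_set(x, np.full(1000, 3.0))
        w, _ = train(
            ts,
            MLPConfig(
                n_inputs=1, hidden=(16,), epochs=500, learning_rate=0.01,
                batch_size=256, patience=100, seed=0,
            ),
        )
        assert np.abs(predict(w, x) - 3.0).mean() < 0.05

    def test_noiseless_linear_map_fit_below_point_one(self):
        rng = np.random.default_rng(1)
        x = rng.random((2000, 2))
        y = 4.0 * x[:, 0] + 2.0 * x[:, 1] + 1.0
        ts = _toy_set(x, y)
        w, _ = train(ts, MLPConfig(n_inputs=2, hidden=(64,), epochs=150, seed=1))
        val_x, val_y = ts.subset("val")
        assert float(np.abs(predict(w, val_x) - val_y).mean()) < 0.1

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        x = rng.random((300, 1))
        ts = _toy_set(x, 2.0 * x[:, 0])
        cfg = MLPConfig(n_inputs=1, hidden=(16,), epochs=20, seed=5)
        w1, h1 = train(ts, cfg)
        w2, h2 = train(ts, cfg)
        assert len(h1) == len(h2)
        for a, b in zip(w1.weights, w2.weights):
            assert np.array_equal(a, b)

    def test_training_loss_decreases_over_trailing_window(self):
        rng = np.random.default_rng(3)
        x = rng.random((1000, 1))
        ts = _toy_set(x, np.sin(3 * x[:, 0]) + 2)
        _, hist = train(ts, MLPConfig(n_inputs=1, hidden=(32,), epochs=60, seed=0))
        losses = [h["train_loss"] for h in hist]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_dimension_mismatch_rejected(self):
        ts = _toy_set(np.random.default_rng(0).random((50, 2)), np.zeros(50))
        with pytest.raises(ValueError):
            train(ts, MLPConfig(n_inputs=3, hidden=(8,)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=0)
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=1, hidden=())
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=1, hidden=(8,) * 5)
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=1, loss="huber")


class TestPredict:
    def test_all_zero_weights_give_zero(self):
        w = MLPWeights(
            (np.zeros((3, 4)), np.zeros((4, 1))),
            (np.zeros(4), np.zeros(1)),
            ("relu", "identity"),
        )
        assert predict(w, np.ones((5, 3))).tolist() == [0.0] * 5

    def test_identity_chain_passes_value_through(self):
        w = MLPWeights(
            (np.array([[1.0]]), np.array([[1.0]])),
            (np.zeros(1), np.zeros(1)),
            ("relu", "identity"),
        )
        assert predict(w, np.array([[2.5]]))[0] == 2.5

    def test_negative_raw_output_clamped_to_zero(self):
        w = MLPWeights(
            (np.array([[1.0]]), np.array([[1.0]])),
            (np.zeros(1), np.array([-0.3])),
            ("relu", "identity"),
        )
        assert w.forward(np.array([[0.0]]))[0] == pytest.approx(-0.3)
        assert predict(w, np.array([[0.0]]))[0] == 0.0

    def test_dimension_mismatch_rejected(self):
        w = MLPWeights((np.ones((2, 1)),), (np.zeros(1),), ("identity",))
        with pytest.raises(ValueError):
            predict(w, np.ones((3, 5)))

    def test_broken_dimension_chain_rejected(self):
        with pytest.raises(ValueError):
            MLPWeights(
                (np.ones((2, 4)), np.ones((3, 1))),
                (np.zeros(4), np.zeros(1)),
                ("relu", "identity"),
            )


class TestEvaluate:
    def test_perfect_predictions_zero_error(self):
        x = np.linspace(0, 1, 20)[:, None]
        w = MLPWeights((np.array([[1.0]]),), (np.zeros(1),), ("identity",))
        ts = _toy_set(x, x[:, 0], val_frac=0.0)
        assert evaluate_mae(w, ts, "train") == 0.0

    def test_known_arithmetic(self):
        # predictions (1, 2) vs targets (2, 4) -> MAE 1.5
        w = MLPWeights((np.array([[1.0]]),), (np.zeros(1),), ("identity",))
        ts = _toy_set(np.array([[1.0], [2.0]]), np.array([2.0, 4.0]), val_frac=0.0)
        assert evaluate_mae(w, ts, "train") == 1.5

    def test_empty_split_rejected(self):
        ts = _toy_set(np.ones((5, 1)), np.ones(5), val_frac=0.0)
        with pytest.raises(ValueError):
            evaluate_mae(
                MLPWeights((np.ones((1, 1)),), (np.zeros(1),), ("identity",)), ts, "test"
            )

    def test_mae_invariant_to_row_shuffling(self, synthetic_year):
        ts = split(extract(synthetic_year[:2000], InputConfig(use_month=False)), seed=0)
        w, _ = train(ts, MLPConfig(n_inputs=2, hidden=(8,), epochs=10, seed=0))
        x, y = ts.subset("test")
        perm = np.random.default_rng(0).permutation(len(y))
        mae1 = float(np.abs(predict(w, x) - y).mean())
        mae2 = float(np.abs(predict(w, x[perm]) - y[perm]).mean())
        assert mae1 == pytest.approx(mae2, abs=1e-12)


class TestGridSearch:
    def test_single_cell_matches_direct_training(self, synthetic_year):
        recs = synthetic_year[:3000]
        cfg = InputConfig(use_zenith=True, use_month=False)
        [res] = grid_search(recs, [cfg], [1], [16], seed=0, n_seeds=1, epochs=15)
        ts = split(extract(recs, cfg), seed=0)
        w, _ = train(ts, MLPConfig(n_inputs=2, hidden=(16,), epochs=15, seed=0))
        assert res.val_mae == pytest.approx(evaluate_mae(w, ts, "val"), abs=1e-12)
        assert isinstance(res, GridResult)

    def test_results_sorted_by_mae(self, synthetic_year):
        res = grid_search(
            synthetic_year[:3000],
            [InputConfig(False, False), InputConfig(True, False)],
            [1],
            [8],
            seed=0,
            n_seeds=1,
            epochs=15,
        )
        assert [r.val_mae for r in res] == sorted(r.val_mae for r in res)

    def test_empty_grid_rejected(self, synthetic_year):
        with pytest.raises(ValueError):
            grid_search(synthetic_year[:100], [], [1], [8], seed=0)

    def test_node_count_outside_grid_choices_rejected(self, synthetic_year):
        with pytest.raises(ValueError):
            grid_search(synthetic_year[:100], [InputConfig()], [1], [12], seed=0)
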