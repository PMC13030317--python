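"""Classifier contracts: builds, metric suite vs a brute-force contingency
oracle, training on separable data, LOPO integrity, baselines, and
serialization."""

import numpy as np
import pytest

from femg_xdyn.model import (
    ARCHITECTURES,
    ModelConfig,
    build_model,
    evaluate,
    load_model,
    lopo_cross_validate,
    permutation_null_macro_f1,
    predict_window,
    retrain_full,
    save_model,
    train,
    train_baseline,
)
from femg_xdyn.types import LABEL_NAMES, N_CLASSES

from conftest import tiny_model_config


def make_separable_windows(n_per_class=12, w=24, seed=0, n_participants=4, noise=0.05):
    """Windows whose class determines which channel group is elevated —
    linearly separable by channel means."""
    rng = np.random.default_rng(seed)
    X, y, pids = [], [], []
    patterns = {0: [], 1: [5, 6, 3, 4], 2: [0, 1, 2], 3: [1, 2]}
    for p in range(n_participants):
        for c in range(N_CLASSES):
            for _ in range(n_per_class):
                win = rng.normal(0, noise, (w, 7))
                for ch in patterns[c]:
                    win[:, ch] += 0.8
                X.append(win)
                y.append(c)
                pids.append(f"P{p:03d}")
    return np.stack(X), np.array(y), np.array(pids)


class TestBuild:
    def test_probabilities_sum_to_one(self):
        model = build_model(tiny_model_config(), 24)
        probs = model.predict_proba(np.random.default_rng(0).standard_normal((5, 24, 7)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initial_parameters(self):
        from femg_xdyn.nn import get_parameters
        a = build_model(tiny_model_config(seed=9), 24)
        b = build_model(tiny_model_config(seed=9), 24)
        for pa, pb in zip(get_parameters(a.net), get_parameters(b.net)):
            np.testing.assert_array_equal(pa, pb)

    def test_window_incompatible_with_pooling_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            build_model(tiny_model_config(), 3)

    def test_invalid_dilation_schedule_rejected(self):
        with pytest.raises(ValueError, match="dilations"):
            tiny_model_config(tcn_dilations=(1, 3)).validate()

    def test_parameter_count_positive(self):
        assert build_model(tiny_model_config(), 24).n_parameters > 1000


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3] * 5)
        probs = np.eye(4)[y] * 0.97 + 0.0075
        m = evaluate(y, y, probs)
        assert m.accuracy == m.macro_f1 == m.weighted_f1 == 1.0
        assert m.roc_auc == 1.0
        np.testing.assert_array_equal(m.confusion, np.eye(4))

    def test_all_predicted_neutral_on_balanced_truth(self):
        y = np.array([0, 1, 2, 3] * 6)
        pred = np.zeros_like(y)
        m = evaluate(y, pred)
        assert m.accuracy == pytest.approx(0.25)
        assert m.macro_recall == pytest.approx(0.25)
        assert m.macro_f1 == pytest.approx(0.10)  # neutral F1 = 0.4, others 0

    def test_matches_contingency_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(8, 60)
            y = rng.integers(0, 4, n)
            p = rng.integers(0, 4, n)
            m = evaluate(y, p)
            # brute-force per-class contingency table
            prec, rec, f1 = [], [], []
            for c in range(4):
                tp = np.sum((p == c) & (y == c))
                fp = np.sum((p == c) & (y != c))
                fn = np.sum((p != c) & (y == c))
                pr = tp / (tp + fp) if tp + fp else 0.0
                rc = tp / (tp + fn) if tp + fn else 0.0
                prec.append(pr)
                rec.append(rc)
                f1.append(2 * pr * rc / (pr + rc) if pr + rc else 0.0)
            assert m.macro_precision == pytest.approx(np.mean(prec))
            assert m.macro_recall == pytest.approx(np.mean(rec))
            assert m.macro_f1 == pytest.approx(np.mean(f1))
            weights = np.bincount(y, minlength=4) / n
            assert m.weighted_f1 == pytest.approx(np.dot(weights, f1))
            assert m.accuracy == pytest.approx(np.mean(y == p))

    def test_macro_metrics_invariant_to_class_permutation(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        base = evaluate(y, p)
        for _ in range(5):
            perm = rng.permutation(4)
            m = evaluate(perm[y], perm[p])
            assert m.macro_f1 == pytest.approx(base.macro_f1)
            assert m.macro_precision == pytest.approx(base.macro_precision)

    def test_probability_rows_must_normalize(self):
        y = np.array([0, 1])
        with pytest.raises(ValueError, match="sum to 1"):
            evaluate(y, y, np.array([[0.5, 0.1, 0.1, 0.1], [0.25] * 4]))


class TestPredictWindow:
    def test_argmax_and_tie_break(self):
        model = build_model(tiny_model_config(), 24)
        label, probs = predict_window(model, np.zeros((24, 7)))
        assert label == LABEL_NAMES[int(probs.argmax())]
        # exact four-way tie resolves to neutral (first in fixed order)
        assert LABEL_NAMES[int(np.argmax([0.25, 0.25, 0.25, 0.25]))] == "neutral"

    def test_wrong_shape_rejected(self):
        model = build_model(tiny_model_config(), 24)
        with pytest.raises(ValueError, match="windows"):
            model.predict_proba(np.zeros((2, 30, 7)))


class TestTrain:
    def test_learns_separable_data(self):
        X, y, _ = make_separable_windows()
        model = build_model(tiny_model_config(max_epochs=10, patience=4), 24)
        hist = train(model, X, y)
        assert evaluate(y, model.predict(X)).accuracy >= 0.99
        assert hist["stopped_epoch"] <= model.config.max_epochs - 1

    def test_empty_and_single_class_rejected(self):
        model = build_model(tiny_model_config(), 24)
        with pytest.raises(ValueError, match="empty"):
            train(model, np.zeros((0, 24, 7)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="2 classes"):
            train(model, np.zeros((4, 24, 7)), np.zeros(4, dtype=int))

    def test_missing_validation_class_warns(self):
        X, y, _ = make_separable_windows(n_per_class=4)
        model = build_model(tiny_model_config(max_epochs=1), 24)
        mask = y < 3
        with pytest.warns(UserWarning, match="missing a class"):
            train(model, X, y, X[mask][:6], y[mask][:6])

    def test_deterministic_given_seed(self):
        X, y, _ = make_separable_windows(n_per_class=4)
        preds = []
        for _ in range(2):
            model = build_model(tiny_model_config(max_epochs=2), 24)
            train(model, X, y)
            preds.append(model.predict_proba(X))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestLOPO:
    def test_fold_structure_and_integrity(self):
        X, y, pids = make_separable_windows(n_per_class=4, n_participants=4)
        res = lopo_cross_validate(X, y, pids, tiny_model_config(max_epochs=2, patience=1))
        held_out = [f.test_participant for f in res.folds]
        assert sorted(held_out) == sorted(np.unique(pids))
        assert len(res.folds) == 4

    def test_rotating_validation_split_is_disjoint(self):
        from femg_xdyn.model import _fold_splits
        participants = [f"P{i}" for i in range(6)]
        for fold in range(6):
            train_p, val_p = _fold_splits(participants, fold, 2)
            assert participants[fold] not in train_p + val_p
            assert not set(train_p) & set(val_p)
            assert len(val_p) == 2

    def test_too_few_participants_rejected(self):
        X, y, pids = make_separable_windows(n_per_class=2, n_participants=2)
        with pytest.raises(ValueError, match=">= 3"):
            lopo_cross_validate(X, y, pids, tiny_model_config())

    def test_learning_signal_exceeds_permutation_null(self):
        X, y, pids = make_separable_windows(n_per_class=6, n_participants=4)
        res = lopo_cross_validate(X, y, pids, tiny_model_config(max_epochs=10, patience=4))
        mean_f1 = res.aggregate("test")["macro_f1"][0]
        # pooled permutation null on one fold's predictions
        model_cfg = tiny_model_config(max_epochs=6, patience=3)
        null = permutation_null_macro_f1(y, y[np.random.default_rng(0).permutation(len(y))],
                                         n_permutations=50)
        assert mean_f1 > null + 0.5
        assert 0.15 < null < 0.35


class TestRetrainAndBaselines:
    def test_retrain_full_and_serialization_round_trip(self, tmp_path):
        X, y, pids = make_separable_windows(n_per_class=4)
        model, hist, metrics = retrain_full(X, y, pids, tiny_model_config(max_epochs=3, patience=2))
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        np.testing.assert_array_equal(model.predict_proba(X[:8]), back.predict_proba(X[:8]))

    def test_retrain_warns_on_missing_participant(self):
        X, y, pids = make_separable_windows(n_per_class=4)
        with pytest.warns(UserWarning, match="missing"):
            retrain_full(X, y, pids, tiny_model_config(max_epochs=1),
                         expected_participants=["P000", "P001", "P002", "P003", "P099"])

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_all_architectures_beat_chance_on_separable_data(self, arch):
        X, y, pids = make_separable_windows(n_per_class=6, w=16, n_participants=4)
        cfg = tiny_model_config(max_epochs=10, patience=4, cnn_filters=(8,),
                                tcn_dilations=(1, 2), tcn_filters=8)
        res = train_baseline(arch, X, y, pids, cfg)
        assert len(res.folds) == 4
        assert res.aggregate("test")["macro_f1"][0] > 0.35

    def test_unknown_architecture_rejected(self):
        X, y, pids = make_separable_windows(n_per_class=2)
        with pytest.raises(ValueError, match="unknown architecture"):
            train_baseline("transformer", X, y, pids, tiny_model_config())
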