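"""Metrics against hand-computed oracles: confusion, F1, one-vs-rest AUC,
learning curves."""

import numpy as np
import pytest

from ltrstack.classification import unified_stacking
from ltrstack.evaluation import (
    EvaluationReport,
    confusion,
    learning_curve,
    roc_auc_ovr,
    scores,
)
from ltrstack.preprocessing import FeatureMatrix
from ltrstack.sequence_io import ClassRegistry, binary_registry


def five_class_registry():
    return ClassRegistry(
        entries={c: ("X", f"class{c}") for c in range(5)}, negative_code=0
    )


def oracle_metrics(cm):
    """Second, formula-level implementation of precision/recall/F1."""
    cm = np.asarray(cm, dtype=float)
    n = cm.shape[0]
    prec, rec, f1 = np.zeros(n), np.zeros(n), np.zeros(n)
    for i in range(n):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec[i] = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec[i] = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1[i] = (
            2 * prec[i] * rec[i] / (prec[i] + rec[i])
            if prec[i] + rec[i] > 0
            else 0.0
        )
    support = cm.sum(axis=1)
    weighted_f1 = (support * f1).sum() / support.sum()
    acc = np.trace(cm) / cm.sum()
    return prec, rec, f1, weighted_f1, acc


def pairwise_auc(y_binary, score):
    """Brute-force AUC: proportion of correctly ordered pos/neg pairs."""
    pos = score[y_binary == 1]
    neg = score[y_binary == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        reg = five_class_registry()
        y = np.repeat(np.arange(5), 20)
        cm = confusion(y, y, reg)
        assert np.trace(cm) == 100
        assert cm.sum() == 100
        assert (cm == np.diag(np.diag(cm))).all()

    def test_single_predicted_class_single_column(self):
        reg = binary_registry()
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.ones(4, dtype=int)
        cm = confusion(y_true, y_pred, reg)
        assert cm[:, 0].sum() == 0 and cm[:, 1].sum() == 4

    def test_absent_registry_class_keeps_zero_row(self):
        reg = five_class_registry()
        cm = confusion([0, 1], [0, 1], reg)
        assert cm.shape == (5, 5)
        assert cm[2:].sum() == 0

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 9], [0, 0], binary_registry())


class TestScores:
    def test_perfect_two_class(self):
        m = scores(np.array([[50, 0], [0, 50]]))
        assert m["accuracy"] == 1.0
        assert (m["f1"] == 1.0).all()

    def test_degenerate_column(self):
        m = scores(np.array([[0, 10], [0, 10]]))
        assert m["recall"][0] == 0.0
        assert m["precision"][1] == 0.5
        assert ("precision", 0) in m["undefined"]

    def test_matches_formula_oracle_on_random_matrices(self, rng):
        reg = five_class_registry()
        for _ in range(20):
            y_true = rng.integers(0, 5, size=200)
            y_pred = rng.integers(0, 5, size=200)
            cm = confusion(y_true, y_pred, reg)
            m = scores(cm)
            prec, rec, f1, wf1, acc = oracle_metrics(cm)
            np.testing.assert_allclose(m["precision"], prec)
            np.testing.assert_allclose(m["recall"], rec)
            np.testing.assert_allclose(m["f1"], f1)
            assert np.isclose(m["weighted"]["f1"], wf1)
            assert np.isclose(m["accuracy"], acc)

    def test_self_confusion_gives_all_ones(self, rng):
        reg = five_class_registry()
        y = rng.integers(0, 5, size=100)
        y[:5] = np.arange(5)  # at least one sample per class
        m = scores(confusion(y, y, reg))
        assert (m["f1"] == 1.0).all()
        assert m["weighted"]["f1"] == 1.0 and m["macro"]["f1"] == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            scores(np.zeros((3, 3)))


class TestAUC:
    def test_constant_scores_give_half(self):
        S = np.full((40, 2), 0.5)
        y = np.array([0] * 20 + [1] * 20)
        out = roc_auc_ovr(S, y, [0, 1])
        assert out["per_class"][0] == 0.5
        assert out["per_class"][1] == 0.5

    def test_perfect_ordering_gives_one(self):
        y = np.array([0] * 10 + [1] * 10)
        s1 = np.concatenate([np.linspace(0, 0.4, 10),
                             np.linspace(0.6, 1.0, 10)])
        S = np.column_stack([1 - s1, s1])
        out = roc_auc_ovr(S, y, [0, 1])
        assert out["per_class"][1] == 1.0
        assert out["macro"] == 1.0

    def test_matches_pairwise_oracle(self, rng):
        n, k = 200, 4
        y = rng.integers(0, k, size=n)
        raw = rng.uniform(size=(n, k))
        S = raw / raw.sum(axis=1, keepdims=True)
        out = roc_auc_ovr(S, y, list(range(k)))
        for c in range(k):
            assert np.isclose(
                out["per_class"][c], pairwise_auc((y == c).astype(int), S[:, c])
            )

    def test_monotone_transform_invariance(self, rng):
        n = 100
        y = rng.integers(0, 2, size=n)
        s = rng.uniform(size=n)
        S = np.column_stack([1 - s, s])
        base = roc_auc_ovr(S, y, [0, 1])["per_class"][1]
        t = np.exp(3 * s)  # strictly increasing transform of class-1 scores
        St = np.column_stack([t.max() * 1.01 - t, t])
        St = St / St.sum(axis=1, keepdims=True)
        from sklearn.metrics import roc_auc_score

        assert np.isclose(roc_auc_score(y, St[:, 1]), base)

    def test_absent_class_excluded_with_warning(self):
        y = np.zeros(10, dtype=int)
        y[:5] = 1
        S = np.column_stack([np.full(10, 0.4), np.full(10, 0.3),
                             np.full(10, 0.3)])
        with pytest.warns(UserWarning):
            out = roc_auc_ovr(S, y, [0, 1, 2])
        assert out["per_class"][2] is None


class TestLearningCurve:
    def _matrix(self):
        from sklearn.datasets import make_blobs

        X, y = make_blobs(n_samples=120, centers=3, cluster_std=4.0,
                          random_state=0)
        return FeatureMatrix(
            X, ["a", "b"], [f"s{i}" for i in range(120)], y
        )

    def test_curve_columns_and_dispersion(self):
        x = self._matrix()
        curve = learning_curve(unified_stacking(0), x, sizes=[0.5, 1.0],
                               k=3, seed=0)
        assert list(curve.columns) == [
            "size", "n_train", "train_mean", "train_std", "cv_mean", "cv_std",
        ]
        assert (curve.train_std >= 0).all() and (curve.cv_std >= 0).all()
        assert curve.n_train.is_monotonic_increasing

    def test_tiny_sizes_skipped_with_warning(self):
        x = self._matrix()
        with pytest.warns(UserWarning, match="skipped"):
            curve = learning_curve(unified_stacking(0), x,
                                   sizes=[0.01, 1.0], k=3, seed=0)
        assert len(curve) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_overfitting_direction_on_separable_data(self, seed):
        from sklearn.datasets import make_blobs

        X, y = make_blobs(n_samples=90, centers=3, cluster_std=1.0,
                          random_state=seed)
        x = FeatureMatrix(X, ["a", "b"], [f"s{i}" for i in range(90)], y)
        curve = learning_curve(unified_stacking(seed), x,
                               sizes=[0.2, 1.0], k=3, seed=seed)
        assert curve.train_mean.iloc[0] >= curve.train_mean.iloc[-1] - 1e-9


class TestReport:
    def test_report_round_trip_and_text(self, rng, tmp_path):
        reg = binary_registry()
        y_true = rng.integers(0, 2, size=60)
        y_pred = rng.integers(0, 2, size=60)
        s = rng.uniform(size=60)
        S = np.column_stack([1 - s, s])
        report = EvaluationReport.from_predictions(y_true, y_pred, reg, S)
        import json

        doc = json.loads(report.to_json(tmp_path / "r.json"))
        assert set(doc["per_class"]) == {"0", "1"}
        assert np.isclose(
            doc["accuracy"], (y_true == y_pred).mean()
        )
        assert "accuracy" in report.to_text()
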