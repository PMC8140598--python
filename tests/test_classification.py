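"""Base classifiers, grid search, stacking ensembles, and the model bundle."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import f1_score

from ltrstack.classification import (
    ClassifierSpec,
    GridSpec,
    ModelBundle,
    default_grid,
    fit_bundle,
    grid_search,
    multiclass_stacking,
    predict,
    train_stacking,
    tuned_spec,
    unified_stacking,
)
from ltrstack.preprocessing import FeatureMatrix, make_folds
from ltrstack.synthetic_data import default_spec, generate


def blob_matrix(n_classes=3, n=90, cluster_std=1.0, seed=0):
    X, y = make_blobs(
        n_samples=n, centers=n_classes, cluster_std=cluster_std,
        random_state=seed,
    )
    return FeatureMatrix(
        X, [f"f{j}" for j in range(X.shape[1])],
        [f"s{i}" for i in range(n)], y,
    )


class TestSpecs:
    def test_tuned_defaults_for_retained_algorithms(self):
        assert tuned_spec("KNN").hyperparameters == {
            "neighbors": 2, "weights": "distance", "metric": "euclidean",
            "algorithm": "auto",
        }
        assert tuned_spec("LinearSVC").hyperparameters == {
            "C": 0.001, "penalty": "l2", "loss": "squared_hinge", "tol": 0.1,
        }
        assert tuned_spec("LR").hyperparameters == {
            "C": 0.01, "tol": 10.0, "max_iter": 1000, "penalty": "l2",
            "solver": "sag",
        }
        assert tuned_spec("LDA").hyperparameters == {
            "shrinkage": 0.0001, "solver": "lsqr", "tol": 0.1,
        }

    def test_default_grids_reproduce_tuning_ranges(self):
        knn = default_grid("KNN")
        assert knn.grid["neighbors"] == [2, 20, 39, 57, 76, 94, 113, 131, 150]
        assert len(knn.grid["weights"]) == 2
        assert len(knn.grid["metric"]) == 7
        assert len(knn.grid["algorithm"]) == 4
        assert len(knn.candidates()) == 9 * 2 * 7 * 4
        svc = default_grid("LinearSVC")
        assert svc.grid["C"] == [10.0 ** i for i in range(-4, 6)]
        lr = default_grid("LR")
        assert lr.grid["solver"].count("saga") == 1  # printed duplicate removed
        assert lr.grid["penalty"] == ["l1", "l2", "elasticnet", "none"]

    def test_all_eight_algorithms_build(self):
        for alg in ("KNN", "LinearSVC", "LR", "LDA", "NB", "MLP", "DT", "RF"):
            est = ClassifierSpec(alg).build() if alg not in (
                "KNN", "LinearSVC", "LR", "LDA"
            ) else tuned_spec(alg).build()
            assert hasattr(est, "fit")

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("SVM9000")

    def test_default_stacking_compositions(self):
        mc = multiclass_stacking()
        assert [s.algorithm for s in mc.base] == ["LDA", "LinearSVC", "KNN"]
        assert mc.meta.algorithm == "RF"
        un = unified_stacking()
        assert [s.algorithm for s in un.base] == ["KNN", "LDA", "LR"]
        assert un.meta.algorithm == "RF"


class TestGridSearch:
    def test_single_candidate_returned_with_score(self):
        x = blob_matrix()
        folds = make_folds(np.arange(x.n_samples), k=3, seed=0,
                           stratify_labels=x.labels)
        res = grid_search(
            GridSpec("KNN", {"neighbors": [3]}), x, folds
        )
        assert res.best.hyperparameters == {"neighbors": 3}
        assert 0 <= res.best_score <= 1
        assert len(res.table) == 1

    def test_selected_neighbors_matches_bruteforce_oracle(self):
        # tight, well-separated blobs: small neighborhoods win
        x = blob_matrix(n_classes=4, n=120, cluster_std=3.0, seed=5)
        folds = make_folds(np.arange(x.n_samples), k=4, seed=1,
                           stratify_labels=x.labels)
        grid = GridSpec("KNN", {"neighbors": [1, 5, 15, 40]})
        res = grid_search(grid, x, folds)
        # independent exhaustive re-scoring
        from sklearn.neighbors import KNeighborsClassifier

        best_k, best_score = None, -1
        all_idx = np.arange(x.n_samples)
        for k in grid.grid["neighbors"]:
            scores = []
            for val in folds:
                tr = np.setdiff1d(all_idx, val)
                est = KNeighborsClassifier(n_neighbors=k)
                est.fit(x.values[tr], x.labels[tr])
                scores.append(
                    f1_score(x.labels[val], est.predict(x.values[val]),
                             average="weighted")
                )
            if np.mean(scores) > best_score:
                best_score, best_k = np.mean(scores), k
        assert res.best.hyperparameters["neighbors"] == best_k
        assert np.isclose(res.best_score, best_score)

    def test_failing_candidate_penalized_not_fatal(self):
        x = blob_matrix()
        folds = make_folds(np.arange(x.n_samples), k=3, seed=0)
        # wminkowski metric is invalid in modern estimators -> flagged, score 0
        res = grid_search(
            GridSpec("KNN", {"neighbors": [3], "metric": ["wminkowski",
                                                          "euclidean"]}),
            x, folds,
        )
        table = res.table
        assert bool(table[table.metric == "wminkowski"].failed.iloc[0])
        assert res.best.hyperparameters["metric"] == "euclidean"

    def test_empty_grid_rejected(self):
        x = blob_matrix()
        with pytest.raises(ValueError):
            grid_search(GridSpec("KNN", {}), x, [])


class TestStacking:
    def test_separable_clouds_reach_perfect_f1(self):
        x = blob_matrix(n_classes=2, n=80, cluster_std=0.3, seed=2)
        model = train_stacking(unified_stacking(0), x)
        pred = model.predict(x.values)
        assert f1_score(x.labels, pred, average="weighted") == 1.0

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(0)
        n_classes, reps = 4, 20
        x = blob_matrix(n_classes=n_classes, n=120, cluster_std=0.5, seed=3)
        folds = make_folds(np.arange(x.n_samples), k=3, seed=0)
        all_idx = np.arange(x.n_samples)
        scores = []
        for _ in range(reps):
            y = rng.permutation(x.labels)
            xp = FeatureMatrix(x.values, x.feature_names, x.sample_ids, y)
            fold_scores = []
            for val in folds[:2]:
                tr = np.setdiff1d(all_idx, val)
                m = train_stacking(unified_stacking(0), xp.rows(tr))
                fold_scores.append(
                    f1_score(y[val], m.predict(x.values[val]),
                             average="weighted", zero_division=0)
                )
            scores.append(np.mean(fold_scores))
        chance = 1.0 / n_classes
        se = np.std(scores, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(scores) - chance) < 3 * se + 0.02

    def test_single_class_input_rejected(self):
        x = blob_matrix(n_classes=2, n=40)
        y = np.zeros(40, dtype=int)
        xp = FeatureMatrix(x.values, x.feature_names, x.sample_ids, y)
        with pytest.raises(ValueError):
            train_stacking(unified_stacking(0), xp)

    def test_determinism_under_fixed_seed(self):
        x = blob_matrix(n_classes=3, n=90, cluster_std=2.0, seed=7)
        m1 = train_stacking(unified_stacking(42), x)
        m2 = train_stacking(unified_stacking(42), x)
        np.testing.assert_array_equal(
            m1.predict_proba(x.values), m2.predict_proba(x.values)
        )


@pytest.fixture(scope="module")
def fitted_bundle():
    spec = default_spec(n_per_class=12, separation=1.0, seed=11)
    ds = generate(spec)
    return ds, fit_bundle(ds, k_min=1, k_max=3, seed=11)


class TestBundle:
    def test_training_set_memorized_in_separable_limit(self, fitted_bundle):
        ds, bundle = fitted_bundle
        preds = predict(bundle, ds)
        agree = np.mean(
            [p.code == r.label for p, r in zip(preds, ds.records)]
        )
        assert agree == 1.0

    def test_scores_form_a_distribution(self, fitted_bundle):
        ds, bundle = fitted_bundle
        for p in predict(bundle, ds)[:20]:
            assert (p.scores >= 0).all()
            assert abs(p.scores.sum() - 1.0) < 1e-9

    def test_serialization_round_trip_exact(self, fitted_bundle, tmp_path):
        ds, bundle = fitted_bundle
        before = predict(bundle, ds)
        path = tmp_path / "model.joblib"
        bundle.save(path)
        after = predict(ModelBundle.load(path), ds)
        for a, b in zip(before, after):
            assert a.code == b.code
            np.testing.assert_array_equal(a.scores, b.scores)


class TestTaskDifficulty:
    def test_unified_no_harder_than_binary_on_synthetic_data(self):
        """Weighted F1 of the 14-class unified task never beats the binary
        collapse of the same predictions data (checked over 5 seeds)."""
        from dataclasses import replace
        from ltrstack.kmer_features import enumerate_kmers, vectorize_dataset
        from ltrstack.preprocessing import apply_preprocess, fit_preprocess
        from ltrstack.sequence_io import Dataset, binary_registry

        vocab = enumerate_kmers(1, 3)
        for seed in range(5):
            spec = default_spec(n_per_class=10, separation=0.6, seed=seed)
            ds = generate(spec)
            x = vectorize_dataset(ds, vocab)
            pre = fit_preprocess(x)
            z = apply_preprocess(pre, x)
            folds = make_folds(np.arange(z.n_samples), k=3, seed=seed,
                               stratify_labels=z.labels)
            all_idx = np.arange(z.n_samples)
            f1_unified, f1_binary = [], []
            for val in folds:
                tr = np.setdiff1d(all_idx, val)
                m = train_stacking(unified_stacking(seed), z.rows(tr))
                pred = m.predict(z.values[val])
                f1_unified.append(
                    f1_score(z.labels[val], pred, average="weighted",
                             zero_division=0)
                )
                yb = (z.labels[val] != 0).astype(int)
                pb = (pred != 0).astype(int)
                f1_binary.append(
                    f1_score(yb, pb, average="weighted", zero_division=0)
                )
            assert np.mean(f1_unified) <= np.mean(f1_binary) + 1e-9
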