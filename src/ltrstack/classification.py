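"""Tuned base classifiers, grid-search tuning, and stacking ensembles.

Three tasks share the machinery: binary (LTR retrotransposon vs other genomic
features), multiclass (lineage/family level), and the unified task that folds
the negative class into the lineage problem. The retained base algorithms are
KNN, linear SVC, logistic regression and LDA, each with grid-tunable
hyper-parameters and tuned defaults; the ensemble is a stacking classifier
whose base-learner out-of-fold predictions feed a random-forest
meta-classifier (LDA + LinearSVC + KNN for the multiclass task, KNN + LDA +
LR for the unified task).

A fitted pipeline serializes as a :class:`ModelBundle`: preprocessing, k-mer
vocabulary, optional feature subset, fitted ensemble and class registry in a
single archive, such that predictions survive a save/load round trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .kmer_features import KmerVocabulary, enumerate_kmers, vectorize_dataset
from .numeric_encodings import (
    encode_dataset,
    load_scheme,
    physchem_dataset,
)
from .preprocessing import (
    FeatureMatrix,
    PreprocessModel,
    apply_preprocess,
    fit_preprocess,
)
from .sequence_io import ClassRegistry, Dataset, SequenceRecord

__all__ = [
    "ClassifierSpec",
    "GridSpec",
    "GridSearchResult",
    "StackingSpec",
    "ModelBundle",
    "Prediction",
    "ALGORITHMS",
    "tuned_spec",
    "default_grid",
    "multiclass_stacking",
    "unified_stacking",
    "grid_search",
    "train_stacking",
    "fit_bundle",
    "predict",
]

ALGORITHMS = ("KNN", "LinearSVC", "LR", "LDA", "NB", "MLP", "DT", "RF")

#: Tuned hyper-parameter values retained after the exhaustive grid search.
_TUNED: dict[str, dict[str, object]] = {
    "KNN": {
        "neighbors": 2,
        "weights": "distance",
        "metric": "euclidean",
        "algorithm": "auto",
    },
    "LinearSVC": {"C": 0.001, "penalty": "l2", "loss": "squared_hinge",
                  "tol": 0.1},
    "LR": {"C": 0.01, "tol": 10.0, "max_iter": 1000, "penalty": "l2",
           "solver": "sag"},
    "LDA": {"shrinkage": 0.0001, "solver": "lsqr", "tol": 0.1},
}

#: Exhaustive tuning ranges for the four retained algorithms. The logistic
#: regression solver list is deduplicated ("saga" appeared twice in the
#: source configuration); degenerate combinations (e.g. l1 + hinge) are
#: penalized by the grid-search error rule rather than removed.
_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {
        "neighbors": [2, 20, 39, 57, 76, 94, 113, 131, 150],
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan", "chebyshev", "minkowski",
                   "wminkowski", "seuclidean", "mahalanobis"],
        "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
    },
    "LinearSVC": {
        "C": [10.0 ** i for i in range(-4, 6)],
        "penalty": ["l1", "l2"],
        "loss": ["hinge", "squared_hinge"],
        "tol": [1e-1, 1e-2, 1e-4, 1e-8],
    },
    "LR": {
        "C": [10.0 ** i for i in range(-4, 6)],
        "tol": [10.0 ** i for i in range(-4, 6)],
        "max_iter": [10 ** i for i in range(0, 7)],
        "penalty": ["l1", "l2", "elasticnet", "none"],
        "solver": ["saga", "liblinear", "newton-cg", "lbfgs", "sag"],
    },
    "LDA": {
        "shrinkage": [1, 0.1, 0.5, 0.001, 0.0001, 0.00001],
        "solver": ["svd", "lsqr", "eigen"],
        "tol": [1e-1, 1e-2, 1e-4, 1e-8],
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One algorithm plus hyper-parameters plus seed; builds an estimator."""

    algorithm: str
    hyperparameters: dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {ALGORITHMS}"
            )

    def build(self):
        """Instantiate the scikit-learn estimator for this spec."""
        h = dict(self.hyperparameters)
        alg = self.algorithm
        if alg == "KNN":
            if "neighbors" in h:
                h["n_neighbors"] = h.pop("neighbors")
            return KNeighborsClassifier(**h)
        if alg == "LinearSVC":
            return LinearSVC(random_state=self.seed, **h)
        if alg == "LR":
            if h.get("penalty") == "none":
                h["penalty"] = None
            return LogisticRegression(random_state=self.seed, **h)
        if alg == "LDA":
            return LinearDiscriminantAnalysis(**h)
        if alg == "NB":
            return GaussianNB(**h)
        if alg == "MLP":
            return MLPClassifier(random_state=self.seed, **h)
        if alg == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **h)
        if alg == "RF":
            h.setdefault("n_estimators", 500)
            h.setdefault("class_weight", "balanced")
            return RandomForestClassifier(random_state=self.seed, **h)
        raise AssertionError(alg)


def tuned_spec(algorithm: str, seed: int = 0) -> ClassifierSpec:
    """Tuned defaults for the four retained algorithms (KNN/LinearSVC/LR/LDA).

    Other algorithms (NB, MLP, DT, RF) come with library defaults, to be
    scanned over a single hyper-parameter by the caller.
    """
    return ClassifierSpec(
        algorithm=algorithm,
        hyperparameters=dict(_TUNED.get(algorithm, {})),
        seed=seed,
    )


@dataclass(frozen=True)
class GridSpec:
    """A named algorithm with candidate value lists per hyper-parameter."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def candidates(self) -> list[dict[str, object]]:
        """Cross-product enumeration preserving parameter insertion order."""
        keys = list(self.grid)
        combos = product(*(self.grid[k] for k in keys))
        return [dict(zip(keys, c)) for c in combos]


def default_grid(algorithm: str, seed: int = 0) -> GridSpec:
    """The exhaustive tuning grid for one of the four retained algorithms."""
    if algorithm not in _GRIDS:
        raise KeyError(
            f"no default grid for {algorithm!r}; valid: {tuple(_GRIDS)}"
        )
    return GridSpec(algorithm=algorithm,
                    grid={k: list(v) for k, v in _GRIDS[algorithm].items()},
                    seed=seed)


@dataclass
class GridSearchResult:
    """Best candidate plus the full per-candidate cross-validation table."""

    best: ClassifierSpec
    table: pd.DataFrame  # columns: params (one per name), cv_f1, failed

    @property
    def best_score(self) -> float:
        return float(self.table["cv_f1"].max())


def _fold_pairs(
    n: int, folds: Sequence[np.ndarray]
) -> list[tuple[np.ndarray, np.ndarray]]:
    all_idx = np.arange(n)
    pairs = []
    for val in folds:
        val = np.asarray(val)
        train = np.setdiff1d(all_idx, val)
        pairs.append((train, val))
    return pairs


def grid_search(
    spec: GridSpec,
    x: FeatureMatrix,
    folds: Sequence[np.ndarray],
    metric: str = "f1_weighted",
) -> GridSearchResult:
    """Exhaustive grid search maximizing mean cross-validated weighted F1.

    ``folds`` are validation row-index sets over ``x`` (the complement of
    each is its training set). A candidate that raises or fails to converge
    scores the metric's minimum (0) and is flagged ``failed``, never fatal.
    Ties break toward the first candidate in grid enumeration order.
    """
    if not spec.grid:
        raise ValueError("grid is empty")
    if x.labels is None:
        raise ValueError("feature matrix must carry labels")
    average = metric.split("_", 1)[1] if "_" in metric else "weighted"
    pairs = _fold_pairs(x.n_samples, folds)
    rows = []
    best_idx, best_score = None, -np.inf
    for i, params in enumerate(spec.candidates()):
        cand = ClassifierSpec(spec.algorithm, params, seed=spec.seed)
        scores, failed = [], False
        for train_idx, val_idx in pairs:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", ConvergenceWarning)
                    est = cand.build()
                    est.fit(x.values[train_idx], x.labels[train_idx])
                    pred = est.predict(x.values[val_idx])
                scores.append(
                    f1_score(x.labels[val_idx], pred, average=average,
                             zero_division=0)
                )
            except Exception:
                failed = True
                scores.append(0.0)
        mean = float(np.mean(scores))
        if failed:
            mean = 0.0
        rows.append({**params, "cv_f1": mean, "failed": failed})
        if mean > best_score:
            best_score, best_idx = mean, i
    table = pd.DataFrame(rows)
    best_params = spec.candidates()[best_idx]
    return GridSearchResult(
        best=ClassifierSpec(spec.algorithm, best_params, seed=spec.seed),
        table=table,
    )


# ---------------------------------------------------------------------------
# Stacking ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackingSpec:
    """Base learner list + random-forest meta-classifier + task tag."""

    base: tuple[ClassifierSpec, ...]
    meta: ClassifierSpec
    task: str = "multiclass"
    internal_folds: int = 5

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass", "unified"):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.base:
            raise ValueError("at least one base classifier required")

    def build(self) -> StackingClassifier:
        estimators = [
            (f"{s.algorithm.lower()}_{i}", s.build())
            for i, s in enumerate(self.base)
        ]
        cv = KFold(
            n_splits=self.internal_folds, shuffle=True,
            random_state=self.meta.seed,
        )
        return StackingClassifier(
            estimators=estimators,
            final_estimator=self.meta.build(),
            cv=cv,
            stack_method="auto",
            n_jobs=1,
        )


def _meta_rf(seed: int) -> ClassifierSpec:
    return ClassifierSpec(
        "RF",
        {"n_estimators": 500, "class_weight": "balanced"},
        seed=seed,
    )


def multiclass_stacking(seed: int = 0) -> StackingSpec:
    """Lineage-level ensemble: LDA + LinearSVC + KNN over a RF meta-learner."""
    return StackingSpec(
        base=(
            tuned_spec("LDA", seed),
            tuned_spec("LinearSVC", seed),
            tuned_spec("KNN", seed),
        ),
        meta=_meta_rf(seed),
        task="multiclass",
    )


def unified_stacking(seed: int = 0) -> StackingSpec:
    """Unified-task ensemble: KNN + LDA + LR over a RF meta-learner."""
    return StackingSpec(
        base=(
            tuned_spec("KNN", seed),
            tuned_spec("LDA", seed),
            tuned_spec("LR", seed),
        ),
        meta=_meta_rf(seed),
        task="unified",
    )


def train_stacking(
    spec: StackingSpec, x: FeatureMatrix, labels: Optional[np.ndarray] = None
) -> StackingClassifier:
    """Fit the stacking ensemble: base learners on the training rows, the
    meta-learner on seeded out-of-fold base predictions.

    Deterministic under the specs' seeds; single-class input is an error.
    """
    y = x.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ValueError("labels required")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    model = spec.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x.values, y)
    return model


# ---------------------------------------------------------------------------
# End-to-end bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    """Per-record output: hard class code + scores over registry classes."""

    id: str
    code: Optional[int]
    scores: Optional[np.ndarray]
    error: Optional[str] = None


@dataclass
class ModelBundle:
    """Everything needed to classify new FASTA records.

    Bundles the fitted preprocessing, the k-mer vocabulary, the optional
    selected-feature subset, the fitted stacking ensemble and the class
    registry, plus provenance (config hash and seeds) for reproducibility.
    """

    preprocess: PreprocessModel
    vocabulary: KmerVocabulary
    stacking_spec: StackingSpec
    model: StackingClassifier
    registry: ClassRegistry
    selected_features: Optional[list[str]] = None
    feature_mode: str = "kmer"  # or "encoded" / "physchem" (binary task)
    scheme_name: Optional[str] = None
    pad_to: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def _config_hash(*parts: object) -> str:
    blob = json.dumps([repr(p) for p in parts], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _featurize(
    ds: Dataset,
    vocab: KmerVocabulary,
    feature_mode: str,
    scheme_name: Optional[str],
    pad_to: Optional[int],
) -> FeatureMatrix:
    if feature_mode == "kmer":
        return vectorize_dataset(ds, vocab)
    if feature_mode == "encoded":
        if scheme_name is None:
            raise ValueError("encoded feature mode requires a scheme name")
        return encode_dataset(ds, load_scheme(scheme_name), pad_to=pad_to)
    if feature_mode == "physchem":
        return physchem_dataset(ds, pad_to=pad_to)
    raise ValueError(f"unknown feature mode {feature_mode!r}")


def fit_bundle(
    train: Dataset,
    spec: Optional[StackingSpec] = None,
    k_min: int = 1,
    k_max: int = 6,
    selected_features: Optional[Sequence[str]] = None,
    variance_target: float = 0.96,
    tolerance: float = 1e-4,
    seed: int = 0,
    vocabulary: Optional[KmerVocabulary] = None,
    features: Optional[FeatureMatrix] = None,
    feature_mode: str = "kmer",
    scheme_name: Optional[str] = None,
) -> ModelBundle:
    """Fit the full pipeline on a labeled dataset.

    Featurizes (unless a precomputed ``features`` matrix is supplied), slices
    to the selected feature subset if given, fits scaling + PCA on the
    training rows, and trains the stacking ensemble. ``feature_mode`` is
    "kmer" (default, all tasks) or "encoded"/"physchem" (numeric-series
    alternatives used for the binary task).
    """
    spec = spec or unified_stacking(seed)
    vocab = vocabulary or enumerate_kmers(k_min, k_max)
    if features is not None:
        x = features
    else:
        x = _featurize(train, vocab, feature_mode, scheme_name, None)
    pad_to = x.n_features if feature_mode == "encoded" else (
        x.n_features // 3 if feature_mode == "physchem" else None
    )
    if x.labels is None:
        raise ValueError("training dataset must be fully labeled")
    subset = None
    if selected_features is not None:
        subset = list(selected_features)
        x = x.select(subset)
    pre = fit_preprocess(x, variance_target=variance_target,
                         tolerance=tolerance)
    z = apply_preprocess(pre, x)
    model = train_stacking(spec, z)
    return ModelBundle(
        preprocess=pre,
        vocabulary=vocab,
        stacking_spec=spec,
        model=model,
        registry=train.registry,
        selected_features=subset,
        feature_mode=feature_mode,
        scheme_name=scheme_name,
        pad_to=pad_to,
        provenance={
            "seed": seed,
            "config_hash": _config_hash(spec, vocab.k_min, vocab.k_max,
                                        subset, variance_target, seed,
                                        feature_mode, scheme_name),
            "n_train": x.n_samples,
        },
    )


def predict(bundle: ModelBundle, ds: Dataset) -> list[Prediction]:
    """Classify every record of a dataset with a fitted bundle.

    Pipeline: k-mer counts -> optional feature subset -> scaling + PCA ->
    stacking ensemble. Returns, per record, the hard class code and a score
    vector over all registry classes (non-negative, summing to 1; classes the
    model never saw score 0). A record that cannot be featurized yields an
    error entry, not a batch failure.
    """
    results: list[Optional[Prediction]] = [None] * len(ds)
    good_records: list[SequenceRecord] = []
    good_pos: list[int] = []
    for i, rec in enumerate(ds):
        if len(rec.residues) == 0:
            results[i] = Prediction(rec.id, None, None, "empty sequence")
        else:
            good_records.append(rec)
            good_pos.append(i)
    if good_records:
        sub = Dataset(good_records, ds.registry)
        x = _featurize(sub, bundle.vocabulary, bundle.feature_mode,
                       bundle.scheme_name, bundle.pad_to)
        if bundle.selected_features is not None:
            x = x.select(bundle.selected_features)
        z = apply_preprocess(bundle.preprocess, x)
        proba = bundle.model.predict_proba(z.values)
        model_classes = list(bundle.model.classes_)
        registry_codes = bundle.registry.codes
        for row, rec, pos in zip(proba, good_records, good_pos):
            scores = np.zeros(len(registry_codes))
            for j, cls in enumerate(model_classes):
                scores[registry_codes.index(int(cls))] = row[j]
            code = int(model_classes[int(np.argmax(row))])
            results[pos] = Prediction(rec.id, code, scores)
    return results  # type: ignore[return-value]
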