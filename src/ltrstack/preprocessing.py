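"""Feature scaling, PCA dimension reduction, and data splitting.

The pipeline standardizes each feature on the training data, then projects
onto the smallest set of principal components whose cumulative explained
variance reaches the target (default 96%). Splits follow the 80/10/10
train/validation/test scheme with optional stratification, and k-fold
cross-validation indices (default k = 9) are drawn from the training domain.
Fitting happens on training rows only, so no test statistics leak into the
transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler, StandardScaler

__all__ = [
    "FeatureMatrix",
    "PreprocessModel",
    "SplitPlan",
    "fit_preprocess",
    "apply_preprocess",
    "make_split",
    "make_folds",
]


@dataclass
class FeatureMatrix:
    """Samples x named numeric features, with aligned labels and sample ids."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} ids for {n} rows")
        if np.issubdtype(self.values.dtype, np.floating) and not np.isfinite(
            self.values
        ).all():
            raise ValueError("values contain NaN or infinity")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must align with rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order; unknown names raise KeyError."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        cols = [index[n] for n in names]
        return FeatureMatrix(
            self.values[:, cols], list(names), list(self.sample_ids),
            None if self.labels is None else self.labels.copy(),
        )

    def rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx],
            list(self.feature_names),
            [self.sample_ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.feature_names, index=self.sample_ids
        )
        if self.labels is not None:
            df.insert(0, "__label__", self.labels)
        return df

    def write_csv(self, path: str | Path) -> None:
        """Persist as (optionally gzip-compressed, by extension) CSV."""
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        labels = None
        if "__label__" in df.columns:
            labels = df.pop("__label__").to_numpy()
        return cls(
            df.to_numpy(), list(df.columns), [str(i) for i in df.index], labels
        )


@dataclass
class PreprocessModel:
    """Fitted scaling + PCA transform.

    ``tolerance`` is the convergence tolerance handed to the decomposition
    when an iterative solver is used; the default full SVD is exact and
    ignores it.
    """

    scaler: object
    pca: PCA
    feature_names: list[str]
    variance_target: float
    tolerance: float

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def fit_preprocess(
    train: FeatureMatrix,
    variance_target: float = 0.96,
    tolerance: float = 1e-4,
    scaling: str = "standard",
    svd_solver: str = "full",
) -> PreprocessModel:
    """Fit per-feature scaling and PCA on training rows only.

    The number of retained components is the smallest achieving cumulative
    explained variance >= ``variance_target``; ``variance_target = 1.0``
    retains the full rank, min(n_samples - 1, n_features).
    """
    if train.n_samples < 2:
        raise ValueError("need at least 2 training rows to fit")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError(
            f"variance_target must be in (0, 1], got {variance_target}"
        )
    if scaling == "standard":
        scaler = StandardScaler()
    elif scaling == "minmax":
        scaler = MinMaxScaler()
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scaled = scaler.fit_transform(train.values.astype(float))

    max_rank = min(train.n_samples - 1, train.n_features)
    if variance_target >= 1.0:
        n_components: float | int = max_rank
    else:
        n_components = variance_target
    kwargs = {}
    if svd_solver in ("arpack", "randomized"):
        kwargs["tol"] = tolerance
    pca = PCA(n_components=n_components, svd_solver=svd_solver,
              random_state=0, **kwargs)
    pca.fit(scaled)
    return PreprocessModel(
        scaler=scaler,
        pca=pca,
        feature_names=list(train.feature_names),
        variance_target=variance_target,
        tolerance=tolerance,
    )


def apply_preprocess(m: PreprocessModel, x: FeatureMatrix) -> FeatureMatrix:
    """Scale then project a matrix with a fitted model.

    The input must carry exactly the feature names the model was fitted on,
    in the same order.
    """
    if list(x.feature_names) != m.feature_names:
        extra = sorted(set(x.feature_names) - set(m.feature_names))
        missing = sorted(set(m.feature_names) - set(x.feature_names))
        raise ValueError(
            "feature names differ from the fitted model; "
            f"missing={missing[:5]}... extra={extra[:5]}..."
            if missing or extra
            else "feature names are reordered relative to the fitted model"
        )
    scores = m.pca.transform(m.scaler.transform(x.values.astype(float)))
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return FeatureMatrix(
        scores, names, list(x.sample_ids),
        None if x.labels is None else x.labels.copy(),
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Disjoint train/validation/test row indices, optionally with CV folds."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int
    folds: Optional[list[np.ndarray]] = None

    def to_json(self, path: str | Path) -> None:
        doc = {
            "fractions": list(self.fractions),
            "seed": self.seed,
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
            "folds": None
            if self.folds is None
            else [f.tolist() for f in self.folds],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        doc = json.loads(Path(path).read_text())
        return cls(
            train=np.array(doc["train"], dtype=int),
            validation=np.array(doc["validation"], dtype=int),
            test=np.array(doc["test"], dtype=int),
            fractions=tuple(doc["fractions"]),
            seed=doc["seed"],
            folds=None
            if doc["folds"] is None
            else [np.array(f, dtype=int) for f in doc["folds"]],
        )


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Deterministic integer part sizes summing to n (largest remainder)."""
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    short = n - sum(sizes)
    order = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - sizes[i]), reverse=True
    )
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def make_split(
    n: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratify_labels: Optional[Sequence[int]] = None,
) -> SplitPlan:
    """Deterministic 3-way split of ``range(n)``.

    Stratified when labels are given: each class is allocated to the parts by
    largest remainder, so per-part class proportions match the global
    fractions within one sample. Classes with fewer than 3 members go
    entirely to training, with a warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    if stratify_labels is None:
        perm = rng.permutation(n)
        sizes = _largest_remainder(n, fractions)
        bounds = np.cumsum([0] + sizes)
        for p in range(3):
            parts[p] = list(perm[bounds[p] : bounds[p + 1]])
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape != (n,):
            raise ValueError("stratify_labels must have length n")
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            if len(idx) < 3:
                warnings.warn(
                    f"class {cls} has {len(idx)} member(s); "
                    "placed entirely in training"
                )
                parts[0].extend(idx.tolist())
                continue
            sizes = _largest_remainder(len(idx), fractions)
            bounds = np.cumsum([0] + sizes)
            for p in range(3):
                parts[p].extend(idx[bounds[p] : bounds[p + 1]].tolist())
    return SplitPlan(
        train=np.array(sorted(parts[0]), dtype=int),
        validation=np.array(sorted(parts[1]), dtype=int),
        test=np.array(sorted(parts[2]), dtype=int),
        fractions=tuple(fractions),
        seed=seed,
    )


def make_folds(
    train_indices: Sequence[int],
    k: int = 9,
    seed: int = 0,
    stratify_labels: Optional[Sequence[int]] = None,
) -> list[np.ndarray]:
    """Partition ``train_indices`` into k disjoint validation folds.

    Fold sizes differ by at most one. When labels (aligned with
    ``train_indices``) are given, folds are stratified.
    """
    train_indices = np.asarray(train_indices)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(train_indices):
        raise ValueError(
            f"k={k} exceeds number of training samples {len(train_indices)}"
        )
    if stratify_labels is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(train_indices)
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape != train_indices.shape:
            raise ValueError("stratify_labels must align with train_indices")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(train_indices, labels)
    return [np.sort(train_indices[val]) for _, val in split]
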