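"""Reference end-to-end experiments on synthetic data.

These drive the whole pipeline at desk scale — generate a labeled dataset,
featurize, preprocess, cross-validate the stacking ensemble, and optionally
repeat after importance-based feature reduction — and return the measured
quantities. They are what the reproduction script and the recovery tests run.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .classification import StackingSpec, unified_stacking
from .evaluation import cross_validate_stacking
from .feature_selection import (
    BoosterConfig,
    score_importance,
    select_top_fraction,
)
from .kmer_features import enumerate_kmers, vectorize_dataset
from .preprocessing import apply_preprocess, fit_preprocess, make_folds
from .synthetic_data import default_spec, generate

__all__ = ["unified_recovery_experiment", "binary_experiment"]


def unified_recovery_experiment(
    seed: int = 0,
    n_per_class: int = 100,
    separation: float = 1.0,
    k_min: int = 1,
    k_max: int = 6,
    folds: int = 9,
    variance_target: float = 0.96,
    spec: Optional[StackingSpec] = None,
    booster: Optional[BoosterConfig] = None,
    top_fraction: float = 0.05,
) -> dict:
    """Unified-task (negative + 13 lineages) label-recovery experiment.

    Generates a balanced synthetic dataset, counts k-mers, scales + projects
    (PCA at the cumulative-variance target), and estimates the stacking
    ensemble's weighted F1 under stratified k-fold cross-validation. When a
    booster config is given, additionally scores k-mer importance on the full
    count matrix, keeps the top ``top_fraction`` of features, and
    cross-validates again on the reduced matrix.

    Returns a dict with per-fold and mean/std F1 for the full (and, if
    requested, reduced) feature set, plus bookkeeping (n_samples,
    n_features, n_components, n_selected).
    """
    data_spec = default_spec(
        n_per_class=n_per_class, separation=separation, seed=seed
    )
    ds = generate(data_spec)
    vocab = enumerate_kmers(k_min, k_max)
    x = vectorize_dataset(ds, vocab)
    ens = spec or unified_stacking(seed)
    fold_sets = make_folds(
        np.arange(x.n_samples), k=folds, seed=seed, stratify_labels=x.labels
    )

    def cv_on(matrix) -> tuple[np.ndarray, int]:
        pre = fit_preprocess(matrix, variance_target=variance_target)
        z = apply_preprocess(pre, matrix)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cross_validate_stacking(ens, z, fold_sets), pre.n_components

    full_scores, n_components = cv_on(x)
    out = {
        "n_samples": x.n_samples,
        "n_features": x.n_features,
        "n_classes": len(np.unique(x.labels)),
        "n_components": n_components,
        "separation": separation,
        "cv_f1_per_fold": full_scores,
        "cv_f1_mean": float(full_scores.mean()),
        "cv_f1_std": float(full_scores.std()),
    }
    if booster is not None:
        table = score_importance(x, config=booster)
        subset = select_top_fraction(table, top_fraction)
        reduced_scores, n_red_components = cv_on(x.select(subset))
        out.update(
            {
                "n_selected": len(subset),
                "reduced_cv_f1_per_fold": reduced_scores,
                "reduced_cv_f1_mean": float(reduced_scores.mean()),
                "reduced_cv_f1_std": float(reduced_scores.std()),
                "reduced_n_components": n_red_components,
            }
        )
    return out


def binary_experiment(
    seed: int = 0,
    n_per_class: int = 100,
    separation: float = 1.0,
    k_min: int = 1,
    k_max: int = 6,
    variance_target: float = 0.96,
) -> dict:
    """Binary task: LTR retrotransposons vs other genomic features.

    Balanced-samples positives and negatives from a synthetic pool, fits the
    stacking ensemble on an 80/10/10 split's training rows and reports the
    held-out test weighted F1.
    """
    from sklearn.metrics import f1_score

    from .classification import train_stacking
    from .preprocessing import make_split
    from .sequence_io import balanced_sample

    data_spec = default_spec(
        n_per_class=max(2, n_per_class // 4), separation=separation, seed=seed
    )
    ds = generate(data_spec)
    neg_code = ds.registry.negative_code
    from .sequence_io import Dataset

    positives = Dataset(
        [r for r in ds.records if r.label != neg_code], ds.registry
    )
    # enlarge the negative pool to match the positive pool size
    neg_spec = default_spec(
        n_per_class=n_per_class, separation=separation, seed=seed + 1
    )
    negatives = Dataset(
        [r for r in generate(neg_spec).records if r.label == neg_code],
        ds.registry,
    )
    n_draw = min(len(positives), len(negatives), n_per_class)
    sample = balanced_sample(positives, negatives, n_draw, seed=seed)
    vocab = enumerate_kmers(k_min, k_max)
    x = vectorize_dataset(sample, vocab)
    plan = make_split(x.n_samples, seed=seed, stratify_labels=x.labels)
    pre = fit_preprocess(x.rows(plan.train), variance_target=variance_target)
    z_train = apply_preprocess(pre, x.rows(plan.train))
    z_test = apply_preprocess(pre, x.rows(plan.test))
    ens = unified_stacking(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_stacking(ens, z_train)
        pred = model.predict(z_test.values)
    f1 = float(
        f1_score(z_test.labels, pred, average="weighted", zero_division=0)
    )
    return {
        "n_samples": x.n_samples,
        "n_train": len(plan.train),
        "n_test": len(plan.test),
        "test_f1": f1,
    }
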