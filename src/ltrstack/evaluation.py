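"""Metrics: F1 / precision / recall / accuracy, confusion matrices,
one-vs-rest ROC AUC, and learning curves.

Multi-class aggregates default to support-weighted averaging, which is robust
to the severe lineage imbalance of curated repeat libraries (macro averages
are also reported). Undefined precision/recall (empty denominators) are
reported as 0 and flagged rather than dropped, so aggregates stay defined for
rare classes. Multi-class ROC is one-vs-rest with a macro average over the
classes that have both positives and negatives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classification import StackingSpec, train_stacking
from .preprocessing import FeatureMatrix
from .sequence_io import ClassRegistry

__all__ = [
    "EvaluationReport",
    "confusion",
    "scores",
    "roc_auc_ovr",
    "learning_curve",
    "cross_validate_stacking",
]


def confusion(
    labels_true: Sequence[int],
    labels_pred: Sequence[int],
    registry: ClassRegistry,
) -> np.ndarray:
    """Confusion matrix over all registry codes in ascending order.

    Rows are true classes, columns predicted; classes absent from the data
    contribute zero rows/columns. Labels outside the registry are an error.
    """
    y_true = np.asarray(labels_true)
    y_pred = np.asarray(labels_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    codes = registry.codes
    unknown = set(np.unique(np.concatenate([y_true, y_pred]))) - set(codes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in registry {codes}")
    return _sk_confusion(y_true, y_pred, labels=codes)


def scores(cm: np.ndarray, class_codes: Optional[Sequence[int]] = None) -> dict:
    """Per-class and aggregate metrics from a confusion matrix.

    Returns a dict with per-class precision/recall/f1/support, accuracy, and
    weighted + macro aggregates. Empty denominators yield 0 and the class is
    listed under ``undefined``.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    n_classes = cm.shape[0]
    codes = list(class_codes) if class_codes is not None else list(range(n_classes))
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    diag = np.diag(cm).astype(float)
    undefined = []
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    for i in range(n_classes):
        if predicted[i] > 0:
            precision[i] = diag[i] / predicted[i]
        elif support[i] > 0:
            undefined.append(("precision", codes[i]))
        if support[i] > 0:
            recall[i] = diag[i] / support[i]
        else:
            undefined.append(("recall", codes[i]))
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    total = cm.sum()
    weights = support / total
    return {
        "codes": codes,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": support,
        "accuracy": float(diag.sum() / total),
        "weighted": {
            "precision": float(weights @ precision),
            "recall": float(weights @ recall),
            "f1": float(weights @ f1),
        },
        "macro": {
            "precision": float(precision[support > 0].mean()),
            "recall": float(recall[support > 0].mean()),
            "f1": float(f1[support > 0].mean()),
        },
        "undefined": undefined,
    }


def roc_auc_ovr(
    scores_matrix: np.ndarray,
    labels_true: Sequence[int],
    class_codes: Sequence[int],
) -> dict:
    """One-vs-rest AUC per class plus the macro average.

    ``scores_matrix`` columns align with ``class_codes`` and rows sum to 1.
    Classes without both a positive and a negative example are excluded from
    the macro average with a warning.
    """
    S = np.asarray(scores_matrix, dtype=float)
    y = np.asarray(labels_true)
    if S.shape != (len(y), len(class_codes)):
        raise ValueError("scores matrix shape must be (n_samples, n_classes)")
    row_sums = S.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    per_class: dict[int, Optional[float]] = {}
    usable = []
    for j, code in enumerate(class_codes):
        pos = y == code
        if pos.all() or not pos.any():
            warnings.warn(
                f"class {code} lacks positives or negatives; AUC undefined"
            )
            per_class[code] = None
            continue
        auc = float(roc_auc_score(pos.astype(int), S[:, j]))
        per_class[code] = auc
        usable.append(auc)
    return {
        "per_class": per_class,
        "macro": float(np.mean(usable)) if usable else float("nan"),
    }


@dataclass
class EvaluationReport:
    """Aggregated evaluation artifacts for one model on one labeled set."""

    confusion_matrix: np.ndarray
    class_codes: list[int]
    metrics: dict
    auc: Optional[dict] = None
    learning_curve: Optional[pd.DataFrame] = None

    @classmethod
    def from_predictions(
        cls,
        labels_true: Sequence[int],
        labels_pred: Sequence[int],
        registry: ClassRegistry,
        scores_matrix: Optional[np.ndarray] = None,
    ) -> "EvaluationReport":
        cm = confusion(labels_true, labels_pred, registry)
        codes = registry.codes
        metrics = scores(cm, codes)
        auc = None
        if scores_matrix is not None:
            auc = roc_auc_ovr(scores_matrix, labels_true, codes)
        return cls(cm, list(codes), metrics, auc)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        doc = {
            "class_codes": self.class_codes,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.metrics["accuracy"],
            "weighted": self.metrics["weighted"],
            "macro": self.metrics["macro"],
            "per_class": {
                str(c): {
                    "precision": float(self.metrics["precision"][i]),
                    "recall": float(self.metrics["recall"][i]),
                    "f1": float(self.metrics["f1"][i]),
                    "support": int(self.metrics["support"][i]),
                }
                for i, c in enumerate(self.class_codes)
            },
            "auc": None
            if self.auc is None
            else {
                "macro": self.auc["macro"],
                "per_class": {
                    str(c): v for c, v in self.auc["per_class"].items()
                },
            },
            "learning_curve": None
            if self.learning_curve is None
            else self.learning_curve.to_dict(orient="list"),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [f"accuracy: {self.metrics['accuracy']:.4f}"]
        for agg in ("weighted", "macro"):
            m = self.metrics[agg]
            lines.append(
                f"{agg}: precision={m['precision']:.4f} "
                f"recall={m['recall']:.4f} f1={m['f1']:.4f}"
            )
        if self.auc is not None:
            lines.append(f"macro one-vs-rest AUC: {self.auc['macro']:.4f}")
        return "\n".join(lines)


def cross_validate_stacking(
    spec: StackingSpec,
    x: FeatureMatrix,
    folds: Sequence[np.ndarray],
    average: str = "weighted",
) -> np.ndarray:
    """Per-fold F1 of the stacking ensemble over precomputed validation folds."""
    if x.labels is None:
        raise ValueError("labels required")
    all_idx = np.arange(x.n_samples)
    out = []
    for val in folds:
        val = np.asarray(val)
        train = np.setdiff1d(all_idx, val)
        model = train_stacking(spec, x.rows(train))
        pred = model.predict(x.values[val])
        out.append(
            f1_score(x.labels[val], pred, average=average, zero_division=0)
        )
    return np.array(out)


def learning_curve(
    spec: StackingSpec,
    x: FeatureMatrix,
    sizes: Sequence[float],
    k: int = 5,
    seed: int = 0,
    average: str = "weighted",
) -> pd.DataFrame:
    """Train/CV F1 versus training-set size fraction.

    For each size fraction and each of ``k`` stratified folds, a stratified
    random subsample of the fold's training portion is fitted and scored on
    its own training rows and on the held-out fold. Sizes too small to keep
    at least one sample per class are skipped with a warning.

    Returns a table with columns size, n_train, train_mean, train_std,
    cv_mean, cv_std (dispersions are across folds, never negative).
    """
    if x.labels is None:
        raise ValueError("labels required")
    sizes = list(sizes)
    if any(not 0 < s <= 1 for s in sizes) or sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending fractions in (0, 1]")
    y = x.labels
    n_classes = len(np.unique(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(x.values, y))
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        tr_scores, cv_scores, n_used = [], [], 0
        skipped = False
        for train_idx, val_idx in splits:
            m = max(1, int(round(size * len(train_idx))))
            if m < n_classes:
                skipped = True
                break
            sub = _stratified_subsample(train_idx, y[train_idx], m, rng)
            if len(np.unique(y[sub])) < n_classes:
                skipped = True
                break
            model = train_stacking(spec, x.rows(sub))
            n_used = len(sub)
            tr_scores.append(
                f1_score(y[sub], model.predict(x.values[sub]),
                         average=average, zero_division=0)
            )
            cv_scores.append(
                f1_score(y[val_idx], model.predict(x.values[val_idx]),
                         average=average, zero_division=0)
            )
        if skipped:
            warnings.warn(
                f"size {size} leaves fewer than one sample per class; skipped"
            )
            continue
        rows.append(
            {
                "size": size,
                "n_train": n_used,
                "train_mean": float(np.mean(tr_scores)),
                "train_std": float(np.std(tr_scores)),
                "cv_mean": float(np.mean(cv_scores)),
                "cv_std": float(np.std(cv_scores)),
            }
        )
    return pd.DataFrame(rows)


def _stratified_subsample(
    idx: np.ndarray, labels: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick m of idx keeping class proportions (at least 1 per class)."""
    classes, counts = np.unique(labels, return_counts=True)
    quota = np.maximum(1, np.floor(m * counts / counts.sum()).astype(int))
    # trim overshoot from the largest classes
    while quota.sum() > m:
        quota[np.argmax(quota)] -= 1
    # distribute shortfall to the largest remaining classes
    while quota.sum() < m:
        room = counts - quota
        quota[np.argmax(room)] += 1
    picked = []
    for cls, q in zip(classes, quota):
        members = idx[labels == cls]
        picked.append(rng.choice(members, size=min(q, len(members)),
                                 replace=False))
    return np.sort(np.concatenate(picked))
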