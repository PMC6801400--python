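"""Nearest-neighbor phenotype classification with LOOCV and holdout accuracy.

The classifier assigns a query sample the majority class among its k
nearest training samples under Euclidean distance on per-probe z-scored
expression, with the standardization fitted on the training fold only (no
leakage).  Because subtracting the training mean shifts query and training
samples alike, only the training-fold standard deviations affect neighbor
ordering; the implementation therefore divides squared coordinate
differences by the fold variances directly.

Conventions: k must be odd (two classes, no vote ties); distance ties at
k=1 resolve to the first sample in canonical (dataset) order; a feature
that is constant in the training fold gets unit scale, contributing a
label-independent offset that cannot change neighbor order.

The prediction error of a signature g is the misclassification count
O(g) = number of samples whose predicted class differs from the observed
class array, and its accuracy is Acc(g) = 100 * (1 - O(g)/n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import ExpressionDataset

__all__ = ["AccuracyResult", "predict_nn", "loocv_accuracy", "holdout_accuracy"]

_VAR_FLOOR = 1e-30


@dataclass(frozen=True)
class AccuracyResult:
    """Outcome of scoring a signature on a set of evaluation samples."""

    n_evaluated: int
    n_misclassified: int
    accuracy_pct: float
    per_sample_predictions: dict[str, str]


def _check_k(k: int, n_train: int) -> None:
    if k < 1 or k % 2 == 0:
        raise ValidationError(f"k must be a positive odd integer, got {k}")
    if k > n_train:
        raise ValidationError(f"k={k} exceeds the {n_train} training samples")


def _safe_var(var: np.ndarray) -> np.ndarray:
    var = np.asarray(var, dtype=float)
    return np.where(np.isfinite(var) & (var > _VAR_FLOOR), var, 1.0)


def _train_variances(X: np.ndarray) -> np.ndarray:
    """Unbiased per-feature variance of a training matrix (samples x features)."""
    if X.shape[0] < 2:
        raise ValidationError("training fold needs at least 2 samples")
    return _safe_var(X.var(axis=0, ddof=1))


def _loocv_fold_variances(X: np.ndarray) -> np.ndarray:
    """Per-fold unbiased feature variances for LOOCV, shape (n, p).

    Row i holds the variance of the training fold that excludes sample i.
    """
    n = X.shape[0]
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    m = n - 1
    total = X.sum(axis=0)
    total_sq = (X * X).sum(axis=0)
    mean = (total[None, :] - X) / m
    var = (total_sq[None, :] - X * X - m * mean**2) / (m - 1)
    return _safe_var(var)


def _loocv_contrib(X: np.ndarray) -> np.ndarray:
    """Scaled squared differences, shape (n, n, p).

    ``contrib[i, j, f]`` is the feature-f contribution to the squared
    distance between held-out sample i and training sample j, under the
    fold-i standardization.  Summing over any feature subset yields the
    LOOCV distance matrix for that signature, which is what lets the
    samplers and the prefix scan reuse one precomputation.
    """
    var = _loocv_fold_variances(X)
    diff2 = (X[:, None, :] - X[None, :, :]) ** 2
    return diff2 / var[:, None, :]


def _majority_predict(d2: np.ndarray, y_case: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k-NN majority vote; rows are queries, columns training samples."""
    if k == 1:
        nearest = np.argmin(d2, axis=1)  # ties -> lowest index = canonical order
        return y_case[nearest]
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = y_case[order].sum(axis=1)
    return votes * 2 > k


def _loocv_predict_case(d2: np.ndarray, y_case: np.ndarray, k: int) -> np.ndarray:
    d2 = d2.copy()
    np.fill_diagonal(d2, np.inf)
    return _majority_predict(d2, y_case, k)


def _accuracy_result(dataset: ExpressionDataset, sample_ids: Sequence[str],
                     pred_case: np.ndarray) -> AccuracyResult:
    truth = np.array([dataset.labels[s] == dataset.case_label for s in sample_ids])
    n = len(sample_ids)
    n_mis = int((pred_case != truth).sum())
    preds = {
        s: (dataset.case_label if p else dataset.control_label)
        for s, p in zip(sample_ids, pred_case)
    }
    return AccuracyResult(
        n_evaluated=n,
        n_misclassified=n_mis,
        accuracy_pct=100.0 * (1.0 - n_mis / n),
        per_sample_predictions=preds,
    )


def predict_nn(
    train: ExpressionDataset,
    probes: Sequence[str],
    query: Sequence[float],
    k: int = 1,
) -> str:
    """Classify one query vector (aligned with ``probes``) from a training set."""
    if len(probes) == 0:
        raise ValidationError("empty probe set")
    q = np.asarray(query, dtype=float)
    if q.shape != (len(probes),):
        raise ValidationError(
            f"query has {q.shape} values, expected {len(probes)} (one per probe)"
        )
    X = train.matrix_for(probes)
    _check_k(k, X.shape[0])
    var = _train_variances(X)
    d2 = (((X - q[None, :]) ** 2) / var[None, :]).sum(axis=1)
    pred = _majority_predict(d2[None, :], train.is_case(), k)[0]
    return train.case_label if pred else train.control_label


def loocv_accuracy(
    dataset: ExpressionDataset,
    probes: Sequence[str],
    k: int = 1,
) -> AccuracyResult:
    """Leave-one-out accuracy of a signature: each sample predicted from the rest."""
    if len(probes) == 0:
        raise ValidationError("empty probe set")
    dataset.require_class_minimum(2)
    X = dataset.matrix_for(probes)
    _check_k(k, X.shape[0] - 1)
    d2 = _loocv_contrib(X).sum(axis=2)
    pred = _loocv_predict_case(d2, dataset.is_case(), k)
    return _accuracy_result(dataset, dataset.sample_ids, pred)


def holdout_accuracy(
    train: ExpressionDataset,
    validation: ExpressionDataset,
    probes: Sequence[str],
    k: int = 1,
) -> AccuracyResult:
    """Blind-validation accuracy: validation samples predicted from training only."""
    if len(probes) == 0:
        raise ValidationError("empty probe set")
    if validation.n_samples == 0:
        raise ValidationError("empty validation part")
    overlap = set(train.sample_ids) & set(validation.sample_ids)
    if overlap:
        raise ValidationError(f"train/validation overlap: {sorted(overlap)[:5]}")
    train.require_class_minimum(1)
    for cls in (train.case_label, train.control_label):
        if int((train.labels == cls).sum()) < 1:
            raise ValidationError(f"class {cls!r} absent from the training part")
    Xt = train.matrix_for(probes)
    Xv = validation.matrix_for(probes)
    _check_k(k, Xt.shape[0])
    var = _train_variances(Xt)
    d2 = (((Xv[:, None, :] - Xt[None, :, :]) ** 2) / var[None, None, :]).sum(axis=2)
    pred = _majority_predict(d2, train.is_case(), k)
    return _accuracy_result(validation, validation.sample_ids, pred)
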