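"""Evaluation: Pearson correlation, ROC/AUC and k-fold cross-validation.

Predictions are continuous efficacies, so AUC needs a binarization rule:
a record counts as positive (an "effective" siRNA) when its *observed*
efficacy is at least the cutoff (default 0.7, configurable everywhere it
appears).  PCC is reported both as the mean of per-fold values and pooled
over all held-out predictions; the mean is what model selection uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold

from sirnadeep.model import ModelConfig, TrainedModel, train, predict
from sirnadeep.thermo import NNParameterTable

DEFAULT_AUC_THRESHOLD = 0.7


@dataclass
class EvalReport:
    pcc: float
    auc: float
    roc_points: list  # (1 - specificity, sensitivity) pairs
    threshold: float
    n: int


def pcc(actual, predicted) -> float:
    """Sample Pearson correlation between observed and predicted efficacies.

    (1/(n−1)) Σ ((X_i−X̄)/σ_X)((Y_i−Ȳ)/σ_Y) with σ the sample (ddof=1)
    standard deviation.  Undefined (raises) when either side has zero
    variance or fewer than two points.
    """
    x = np.asarray(actual, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("PCC needs at least 2 points")
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise ValueError("PCC undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def roc_auc(actual_labels, scores) -> tuple[float, list]:
    """AUC plus the ROC polyline traced over all score thresholds.

    AUC is the Mann–Whitney probability that a random positive outscores a
    random negative, ties counting one half.
    """
    labels = np.asarray(actual_labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def sensitivity_specificity(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """TP/(TP+FN) and TN/(TN+FP)."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("sensitivity/specificity undefined for an empty class")
    return tp / (tp + fn), tn / (tn + fp)


def evaluate(actual, predicted, threshold: float = DEFAULT_AUC_THRESHOLD) -> EvalReport:
    """Score a set of (observed, predicted) efficacies into one report.

    PCC or AUC that is undefined on this sample (zero variance, single
    class) is reported as NaN rather than raising, so degenerate folds in
    cross-validation stay usable.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    try:
        r = pcc(actual, predicted)
    except ValueError:
        r = float("nan")
    labels = (actual >= threshold).astype(int)
    try:
        auc, points = roc_auc(labels, predicted)
    except ValueError:
        auc, points = float("nan"), []
    return EvalReport(pcc=r, auc=auc, roc_points=points, threshold=threshold, n=actual.size)


@dataclass
class CVResult:
    fold_reports: list
    pooled: EvalReport
    seed: int
    k: int

    @property
    def mean_pcc(self) -> float:
        vals = [r.pcc for r in self.fold_reports if np.isfinite(r.pcc)]
        return float(np.mean(vals)) if vals else self.pooled.pcc

    @property
    def mean_auc(self) -> float:
        vals = [r.auc for r in self.fold_reports if np.isfinite(r.auc)]
        return float(np.mean(vals)) if vals else self.pooled.auc


def cross_validate(
    records: Sequence,
    config: ModelConfig,
    params: NNParameterTable,
    k: int = 10,
    seed: int = 0,
    auc_threshold: float = DEFAULT_AUC_THRESHOLD,
) -> CVResult:
    """k-fold cross-validation of the deep architecture.

    Fold assignment is deterministic given ``seed``; folds are disjoint and
    exhaustive.  Per-fold PCC/AUC are NaN when undefined (e.g. size-1
    folds); the pooled report over all held-out predictions is always
    computed and serves as the aggregate in that case.
    """
    records = list(records)
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of records {len(records)}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    all_actual, all_pred = [], []
    for fold_i, (train_idx, test_idx) in enumerate(kf.split(records)):
        train_recs = [records[i] for i in train_idx]
        test_recs = [records[i] for i in test_idx]
        model = train(train_recs, config, params)
        preds = predict(test_recs, model, params)
        actual = np.array([r.efficacy for r in test_recs], dtype=float)
        fold_reports.append(evaluate(actual, preds, threshold=auc_threshold))
        all_actual.append(actual)
        all_pred.append(preds)
    pooled = evaluate(
        np.concatenate(all_actual), np.concatenate(all_pred), threshold=auc_threshold
    )
    return CVResult(fold_reports=fold_reports, pooled=pooled, seed=seed, k=k)
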