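"""Classifier evaluation: confusion metrics, ROC/AUC, cross-validation,
and comparison of correlated AUCs.

Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP), Accuracy = (TP+TN)/N.
The ROC is swept over all distinct score cutoffs with ties grouped; the
trapezoidal AUC then equals the Mann-Whitney statistic U/(n1*n2) with
ties counted half. Correlated AUCs (two score vectors on the same
samples) are compared with DeLong's variance estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._exceptions import (
    ConfigurationError,
    AlignmentError,
    EmptyInputError,
    InsufficientReplicationError,
    SingleClassError,
)
from .expression import RESPONDER, ExpressionMatrix
from .pls import PLSSignatureClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, predicted, actual, positive_label: str = RESPONDER
    ) -> "ConfusionCounts":
        predicted = np.asarray(predicted)
        actual = np.asarray(actual)
        if predicted.shape != actual.shape:
            raise AlignmentError("predicted and actual label vectors differ in length")
        pp, ap = predicted == positive_label, actual == positive_label
        return cls(
            tp=int(np.sum(pp & ap)),
            tn=int(np.sum(~pp & ~ap)),
            fp=int(np.sum(pp & ~ap)),
            fn=int(np.sum(~pp & ap)),
        )


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_defined: bool
    specificity_defined: bool


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity/specificity/accuracy; zero-denominator ratios are NaN-flagged."""
    if c.n == 0:
        raise EmptyInputError("no predictions to evaluate")
    sens_def, spec_def = (c.tp + c.fn) > 0, (c.tn + c.fp) > 0
    return ConfusionMetrics(
        sensitivity=c.tp / (c.tp + c.fn) if sens_def else math.nan,
        specificity=c.tn / (c.tn + c.fp) if spec_def else math.nan,
        accuracy=(c.tp + c.tn) / c.n,
        sensitivity_defined=sens_def,
        specificity_defined=spec_def,
    )


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels, positive_label: str = RESPONDER) -> ROCCurve:
    """ROC curve and AUC for a score vector.

    Cutoffs sweep the distinct scores from high to low (ties grouped),
    producing points from (0,0) to (1,1); the trapezoidal area equals
    the tie-corrected Mann-Whitney U/(n1*n2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    tps = np.cumsum(p)
    fps = np.cumsum(~p)
    # keep only the last index of each tied score block
    last = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[last] / n_neg, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


# -- DeLong comparison of correlated AUCs ------------------------------------
def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, pos: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    x, y = scores[pos], scores[~pos]
    m, n = x.size, y.size
    rx = _midrank(np.r_[x, y])
    auc = (rx[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rx[:m] - _midrank(x)) / n
    v01 = 1.0 - (rx[m:] - _midrank(y)) / m
    return auc, v10, v01


def compare_auc(scores_a, scores_b, labels, positive_label: str = RESPONDER) -> dict:
    """DeLong two-sided test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same samples (same label
    vector). Returns the two AUCs, their difference and the p-value.
    A zero-variance difference (e.g. a score compared with itself) gives
    p = 1 when the AUCs are equal.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise AlignmentError("score vectors and labels must align sample-for-sample")
    pos = labels == positive_label
    if pos.all() or (~pos).all():
        raise SingleClassError("AUC comparison needs both classes")
    auc_a, v10_a, v01_a = _delong_components(a, pos)
    auc_b, v10_b, v01_b = _delong_components(b, pos)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "diff": float(diff), "p_value": float(p)}


# -- cross-validation --------------------------------------------------------
@dataclass
class CVReport:
    """Per-fold and averaged metrics of repeated stratified k-fold CV."""

    folds: pd.DataFrame  # columns: repeat, fold, accuracy, sensitivity, specificity, auc
    fold_assignments: dict[int, list[list[str]]]
    k: int
    repeats: int
    seed: int
    per_repeat_means: pd.DataFrame = field(init=False)
    means: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        metric_cols = ["accuracy", "sensitivity", "specificity", "auc"]
        self.per_repeat_means = self.folds.groupby("repeat")[metric_cols].mean()
        self.means = self.folds[metric_cols].mean()


def kfold_cv(
    expr: ExpressionMatrix,
    candidate_genes: list[str],
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    n_components: int = 1,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of the signature model.

    Per repeat, samples are partitioned into k stratified folds with a
    seeded shuffle; per fold the classifier (standardization, PLS
    weights and Youden threshold) is refitted on the training folds only
    and evaluated on the held-out fold. Fold AUC is NaN when the test
    fold contains a single class. Deterministic given the seed.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    sub = expr.restrict(candidate_genes)
    X, y = sub.X, sub.y
    samples = np.asarray(sub.sample_ids)
    class_min = min(np.sum(y == c) for c in np.unique(y))
    k_eff = int(min(k, class_min))
    if k_eff < k:
        import warnings

        warnings.warn(
            f"reducing folds from {k} to {k_eff}: smallest class has {class_min} samples",
            UserWarning,
            stacklevel=2,
        )

    rows, assignments = [], {}
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=(seed + rep) % 2**31)
        rep_folds = []
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            model = PLSSignatureClassifier(n_components=n_components).fit(
                X[tr], y[tr], gene_ids=candidate_genes
            )
            scores = model.decision_function(X[te])
            pred = np.where(scores > model.threshold_, RESPONDER, model.negative_label)
            metrics = confusion_metrics(ConfusionCounts.from_predictions(pred, y[te]))
            if len(np.unique(y[te])) == 2:
                auc = roc_auc(scores, y[te]).auc
            else:  # pragma: no cover - only with extreme class imbalance
                auc = math.nan
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "accuracy": metrics.accuracy,
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                    "auc": auc,
                    # training-fold fit diagnostics; must vary across folds
                    # on heterogeneous data (no test-fold leakage)
                    "threshold": model.threshold_,
                    "train_center_first_gene": float(model.center_[0]),
                }
            )
            rep_folds.append(list(samples[te]))
        assignments[rep] = rep_folds
    return CVReport(
        folds=pd.DataFrame(rows), fold_assignments=assignments, k=k_eff, repeats=repeats, seed=seed
    )


def compare_groups_anova(*groups) -> float:
    """One-way ANOVA p-value across >= 2 groups of values."""
    if len(groups) < 2:
        raise InsufficientReplicationError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InsufficientReplicationError("every group needs at least two values")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 1.0  # all values identical: F is 0/0, read as no group effect
    res = stats.f_oneway(*arrays)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def evaluate_model(
    model: PLSSignatureClassifier, expr: ExpressionMatrix
) -> dict:
    """Score a labeled cohort with a fitted model and summarize performance."""
    if not expr.sample_ids:
        raise EmptyInputError("validation set is empty")
    table = model.score_expression(expr)
    actual = expr.labels.loc[table["sample_id"]].to_numpy()
    counts = ConfusionCounts.from_predictions(table["predicted"].to_numpy(), actual)
    metrics = confusion_metrics(counts)
    roc = roc_auc(table["score"].to_numpy(), actual)
    return {
        "scores": table,
        "confusion": counts,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "accuracy": metrics.accuracy,
        "auc": roc.auc,
        "roc": roc,
    }
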