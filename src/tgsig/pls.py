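"""PLS-based gene-signature classifier with ROC-derived threshold.

The model is a linear patient score over k candidate genes,

    Score = sum_i  L_i * W_i,

where L_i is the expression of gene i standardized by the training mean
and SD, and W is a partial-least-squares weight vector: the unit vector
maximizing the squared sample covariance cov^2(X w, y) between the score
and the (+1/-1 coded, centered) response. For one component — the default
for a six-gene signature fitted on a dozen samples — the maximizer has
the closed form w proportional to X'y. A sample is called a responder
when its score exceeds a threshold T chosen on the training ROC by
maximizing Youden's J (sensitivity + specificity - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._version import __version__ as _pkg_version
from ._exceptions import (
    DegenerateInputError,
    MissingGeneError,
    SingleClassError,
)
from .expression import NON_RESPONDER, RESPONDER, ExpressionMatrix


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the training-ROC cutoff scan."""

    threshold: float
    youden_j: float
    accuracy: float
    degenerate: bool  # no cutoff separated the classes at all (J = 0)


def choose_threshold(
    scores: np.ndarray, labels: np.ndarray, positive_label: str = RESPONDER
) -> ThresholdResult:
    """Pick the score cutoff maximizing Youden's J on training data.

    Candidate cutoffs are the midpoints between adjacent distinct sorted
    scores plus one cutoff below the minimum and one above the maximum
    (the all-positive / all-negative calls). Ties on J are broken toward
    maximal accuracy, then toward the lower cutoff; the result is
    deterministic. ``degenerate`` is set when even the best cutoff has
    J = 0, i.e. the scores carry no class information.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("both classes must be present to choose a threshold")

    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best_j = best_acc = -np.inf
    cut = candidates[0]
    for cand in candidates:  # ascending: full ties keep the lower cutoff
        pred = scores > cand
        tp = int(np.sum(pred & pos))
        tn = int(np.sum(~pred & ~pos))
        j = tp / n_pos + tn / n_neg - 1.0
        acc = (tp + tn) / (n_pos + n_neg)
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and acc > best_acc + 1e-12):
            best_j, best_acc, cut = j, acc, float(cand)
    j, acc = best_j, best_acc
    return ThresholdResult(threshold=cut, youden_j=j, accuracy=acc, degenerate=j <= 0.0)


def _pls_weights(Xs: np.ndarray, yc: np.ndarray, n_components: int) -> np.ndarray:
    """PLS1 weight/coefficient vector on standardized X, centered y.

    One component: the unit vector w ∝ X'y (the closed-form maximizer of
    cov^2(Xw, y)). More components: NIPALS with deflation; each
    per-component weight has unit norm, and the aggregated per-gene
    coefficient vector W (P'W)^{-1} q is returned.
    """
    X = Xs.copy()
    y = yc.copy()
    Ws, Ps, qs = [], [], []
    for _ in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p = X.T @ t / tt
        q = float(y @ t / tt)
        X = X - np.outer(t, p)
        y = y - q * t
        Ws.append(w)
        Ps.append(p)
        qs.append(q)
    if not Ws:
        raise DegenerateInputError("response carries no covariance with any gene")
    if len(Ws) == 1:
        return Ws[0]
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    return W @ np.linalg.solve(P.T @ W, np.asarray(qs))


class PLSSignatureClassifier(ClassifierMixin, BaseEstimator):
    """Responder/non-responder classifier scoring a fixed gene signature.

    ``fit(X, y)`` standardizes each gene on the training data, fits the
    PLS weight vector and selects the classification threshold by the
    Youden criterion on the training scores. ``decision_function``
    returns the signature score; ``predict`` applies ``score > T``.

    Parameters
    ----------
    n_components:
        Number of PLS components (default 1, appropriate for a handful
        of genes and very small n).
    threshold:
        Fixed classification threshold; when None (default) it is chosen
        on the training ROC.
    positive_label, negative_label:
        The two class labels; the positive class is predicted for scores
        above the threshold.

    Attributes
    ----------
    weights_ : per-gene weight vector W
    center_, scale_ : training mean and SD per gene
    threshold_ : classification threshold T
    gene_ids_ : gene order the model expects
    threshold_result_ : diagnostics of the cutoff scan (None if fixed T)
    """

    def __init__(
        self,
        n_components: int = 1,
        threshold: float | None = None,
        positive_label: str = RESPONDER,
        negative_label: str = NON_RESPONDER,
    ):
        self.n_components = n_components
        self.threshold = threshold
        self.positive_label = positive_label
        self.negative_label = negative_label

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y, gene_ids: list[str] | None = None) -> "PLSSignatureClassifier":
        if self.n_components < 1:
            raise DegenerateInputError("n_components must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be samples x genes aligned with y")
        labels = set(np.unique(y))
        if labels != {self.positive_label, self.negative_label}:
            if len(labels) < 2:
                raise SingleClassError(f"training data contains a single class: {labels}")
            raise ValueError(f"unexpected labels {labels}")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]

        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(scale == 0)
        if dead.size:
            raise DegenerateInputError(
                f"candidate genes with zero training variance: {[gene_ids[i] for i in dead]}"
            )
        Xs = (X - center) / scale
        y_num = np.where(y == self.positive_label, 1.0, -1.0)
        yc = y_num - y_num.mean()

        self.gene_ids_ = list(gene_ids)
        self.center_ = center
        self.scale_ = scale
        self.weights_ = _pls_weights(Xs, yc, self.n_components)
        self.classes_ = np.array(sorted([self.negative_label, self.positive_label]))

        scores = Xs @ self.weights_
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.threshold_result_ = None
        else:
            result = choose_threshold(scores, y, self.positive_label)
            self.threshold_ = result.threshold
            self.threshold_result_ = result
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signature score per sample: standardized expression dot W."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.gene_ids_):
            raise ValueError(
                f"X must have {len(self.gene_ids_)} columns in the model's gene order"
            )
        return (X - self.center_) / self.scale_ @ self.weights_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > self.threshold_, self.positive_label, self.negative_label)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise DegenerateInputError("model is not fitted")

    # -- ExpressionMatrix convenience ---------------------------------------
    def score_expression(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Score every sample of an :class:`ExpressionMatrix`.

        The matrix is restricted to the model's genes (raising
        :class:`MissingGeneError` if any is absent); returns a table of
        sample, score and predicted label.
        """
        self._check_fitted()
        missing = [g for g in self.gene_ids_ if g not in set(expr.gene_ids)]
        if missing:
            raise MissingGeneError(f"model genes absent from expression matrix: {missing}")
        sub = expr.restrict(self.gene_ids_)
        scores = self.decision_function(sub.X)
        return pd.DataFrame(
            {
                "sample_id": sub.sample_ids,
                "score": scores,
                "predicted": np.where(
                    scores > self.threshold_, self.positive_label, self.negative_label
                ),
            }
        )

    def restandardized(self, expr: ExpressionMatrix) -> "PLSSignatureClassifier":
        """Copy of the model with center/scale refit on ``expr``.

        Weights and threshold transfer across measurement platforms, but
        the stored per-gene center and SD are platform-specific (e.g.
        microarray log2 intensities vs comparative-Ct log2 relative
        quantities). Scoring a cohort from a different platform first
        refits the standardization on that cohort.
        """
        self._check_fitted()
        sub = expr.restrict(self.gene_ids_)
        scale = sub.X.std(axis=0, ddof=1)
        if (scale == 0).any():
            dead = [g for g, s in zip(self.gene_ids_, scale) if s == 0]
            raise DegenerateInputError(f"genes with zero variance in the cohort: {dead}")
        clone = PLSSignatureClassifier(
            n_components=self.n_components,
            threshold=self.threshold_,
            positive_label=self.positive_label,
            negative_label=self.negative_label,
        )
        clone.gene_ids_ = list(self.gene_ids_)
        clone.center_ = sub.X.mean(axis=0)
        clone.scale_ = scale
        clone.weights_ = self.weights_.copy()
        clone.threshold_ = self.threshold_
        clone.threshold_result_ = None
        clone.classes_ = self.classes_.copy()
        return clone

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted model (lossless: floats round-trip exactly)."""
        self._check_fitted()
        doc = {
            "format": "tgsig-pls-model",
            "version": _pkg_version,
            "gene_ids": self.gene_ids_,
            "center": list(map(float, self.center_)),
            "scale": list(map(float, self.scale_)),
            "weights": list(map(float, self.weights_)),
            "threshold": float(self.threshold_),
            "n_components": int(self.n_components),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSSignatureClassifier":
        """Load a model serialized by :meth:`to_json` (path or JSON text)."""
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        doc = json.loads(text)
        if doc.get("format") != "tgsig-pls-model":
            raise ValueError("not a tgsig PLS model document")
        model = cls(
            n_components=doc["n_components"],
            threshold=doc["threshold"],
            positive_label=doc["positive_label"],
            negative_label=doc["negative_label"],
        )
        model.gene_ids_ = list(doc["gene_ids"])
        model.center_ = np.asarray(doc["center"], dtype=float)
        model.scale_ = np.asarray(doc["scale"], dtype=float)
        model.weights_ = np.asarray(doc["weights"], dtype=float)
        model.threshold_ = float(doc["threshold"])
        model.threshold_result_ = None
        model.classes_ = np.array(sorted([doc["negative_label"], doc["positive_label"]]))
        return model


# -- thin functional wrappers ------------------------------------------------
def fit_pls(
    expr: ExpressionMatrix, candidate_genes: list[str], n_components: int = 1
) -> PLSSignatureClassifier:
    """Fit the signature classifier on the candidate genes of a cohort."""
    sub = expr.restrict(candidate_genes)
    return PLSSignatureClassifier(n_components=n_components).fit(
        sub.X, sub.y, gene_ids=candidate_genes
    )


def score_samples(model: PLSSignatureClassifier, expr: ExpressionMatrix) -> pd.DataFrame:
    """Score an expression matrix with a fitted model (sample, score, predicted)."""
    return model.score_expression(expr)
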