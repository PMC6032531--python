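"""PLS signature classifier: weights, scoring, threshold, serialization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import cross_val_score

from tgsig import ExpressionMatrix, PLSSignatureClassifier, choose_threshold, fit_pls
from tgsig._exceptions import DegenerateInputError, MissingGeneError, SingleClassError
from tgsig.datasets import (
    SIGNATURE_GENES,
    SIGNATURE_THRESHOLD,
    SIGNATURE_WEIGHTS,
    load_reference_model,
)
from tgsig.expression import NON_RESPONDER, RESPONDER

from conftest import two_group_labels


def make_xy(seed=0, n=12, p=6, effect=1.5):
    rng = np.random.default_rng(seed)
    y = two_group_labels(n // 2, n - n // 2)
    X = rng.normal(size=(n, p))
    X[y == RESPONDER, : p // 2] += effect
    return X, y


class TestFit:
    def test_single_perfect_gene_gets_positive_weight(self):
        y = two_group_labels(4, 4)
        X = np.where(y == RESPONDER, 1.0, -1.0)[:, None] + np.random.default_rng(0).normal(
            0, 0.01, size=(8, 1)
        )
        model = PLSSignatureClassifier().fit(X, y)
        assert model.weights_.shape == (1,) and model.weights_[0] > 0
        assert (model.predict(X) == y).all()

    def test_weight_signs_match_training_covariance(self):
        X, y = make_xy(3)
        model = PLSSignatureClassifier().fit(X, y)
        y_num = np.where(y == RESPONDER, 1.0, -1.0)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        cov = Xs.T @ (y_num - y_num.mean())
        assert (np.sign(model.weights_) == np.sign(cov)).all()

    def test_unit_norm_weight_maximizes_squared_covariance(self):
        """The closed-form w must beat 1e5 random unit vectors."""
        X, y = make_xy(7)
        model = PLSSignatureClassifier().fit(X, y)
        assert np.isclose(np.linalg.norm(model.weights_), 1.0)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = np.where(y == RESPONDER, 1.0, -1.0)
        yc = yc - yc.mean()

        def cov2(w):
            return ((Xs @ w) @ yc) ** 2

        rng = np.random.default_rng(11)
        V = rng.normal(size=(100_000, 6))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        best_random = np.max(((V @ Xs.T) @ yc) ** 2)
        assert cov2(model.weights_) >= best_random - 1e-9

    def test_first_component_matches_reference_pls(self):
        X, y = make_xy(5)
        model = PLSSignatureClassifier().fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = np.where(y == RESPONDER, 1.0, -1.0)
        ref = PLSRegression(n_components=1, scale=False).fit(Xs, yc - yc.mean())
        w_ref = ref.x_weights_[:, 0]
        w_ref = w_ref * np.sign(w_ref @ model.weights_)
        assert np.allclose(model.weights_, w_ref, atol=1e-10)

    def test_multi_component_improves_training_fit(self):
        X, y = make_xy(9, n=20, p=8, effect=1.0)
        m1 = PLSSignatureClassifier(n_components=1).fit(X, y)
        m2 = PLSSignatureClassifier(n_components=3).fit(X, y)
        assert m2.weights_.shape == (8,)
        assert m2.score(X, y) >= m1.score(X, y) - 1e-12

    def test_zero_variance_gene_named_in_error(self):
        X, y = make_xy(1)
        X[:, 2] = 5.0
        with pytest.raises(DegenerateInputError, match="gene2"):
            PLSSignatureClassifier().fit(X, y, gene_ids=[f"gene{i}" for i in range(6)])

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(SingleClassError):
            PLSSignatureClassifier().fit(X, np.array([RESPONDER] * 6))

    def test_sklearn_protocol(self):
        X, y = make_xy(2)
        model = PLSSignatureClassifier(n_components=1)
        assert clone(model).get_params()["n_components"] == 1
        scores = cross_val_score(model, X, y, cv=3)
        assert scores.shape == (3,)


class TestScoring:
    def test_zero_standardized_vector_scores_zero_and_responder(self):
        model = load_reference_model()
        score = model.decision_function(np.zeros((1, 6)))[0]
        assert score == 0.0
        assert score > SIGNATURE_THRESHOLD
        assert model.predict(np.zeros((1, 6)))[0] == RESPONDER

    def test_score_linearity_in_each_gene(self):
        model = load_reference_model()
        for i, w in enumerate(SIGNATURE_WEIGHTS):
            x = np.zeros((1, 6))
            x[0, i] = 2.5
            assert np.isclose(model.decision_function(x)[0], w * 2.5)

    def test_scores_equal_bruteforce_dot_products(self):
        X, y = make_xy(13, n=16)
        model = PLSSignatureClassifier().fit(X, y)
        rng = np.random.default_rng(14)
        new = rng.normal(size=(100, 6))
        scores = model.decision_function(new)
        manual = np.array(
            [
                sum(
                    (row[i] - model.center_[i]) / model.scale_[i] * model.weights_[i]
                    for i in range(6)
                )
                for row in new
            ]
        )
        assert np.allclose(scores, manual)

    def test_missing_gene_named(self, tiny_matrix):
        model = PLSSignatureClassifier().fit(
            tiny_matrix.X, tiny_matrix.y, gene_ids=["A", "B", "C", "ABSENT"]
        )
        with pytest.raises(MissingGeneError, match="ABSENT"):
            model.score_expression(
                ExpressionMatrix(tiny_matrix.data.loc[["A", "B", "C"]], tiny_matrix.labels)
            )

    def test_fitted_signs_match_published_signature_directions(self):
        """Down-regulated genes get negative weights, up-regulated positive.

        Planting the published directions (MX1, OASL, SPINK1 lower in
        responders; CRK, GRAPL, RNF2 higher) must reproduce the
        published weight-sign pattern (-, -, -, +, +, +).
        """
        rng = np.random.default_rng(21)
        samples = [f"R{i}" for i in range(6)] + [f"N{i}" for i in range(6)]
        labels = pd.Series([RESPONDER] * 6 + [NON_RESPONDER] * 6, index=samples)
        directions = {"MX1": -1, "OASL": -1, "SPINK1": -1, "CRK": 1, "GRAPL": 1, "RNF2": 1}
        data = {}
        for gene in SIGNATURE_GENES:
            base = rng.normal(7, 0.3, 12)
            base[:6] += directions[gene] * 1.0
            data[gene] = base
        expr = ExpressionMatrix(pd.DataFrame(data, index=samples).T, labels)
        model = fit_pls(expr, SIGNATURE_GENES)
        fitted_signs = {g: np.sign(w) for g, w in zip(model.gene_ids_, model.weights_)}
        published_signs = {g: np.sign(w) for g, w in zip(SIGNATURE_GENES, SIGNATURE_WEIGHTS)}
        assert fitted_signs == published_signs


class TestThreshold:
    def test_perfect_separation_midpoint_and_accuracy_one(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([NON_RESPONDER, NON_RESPONDER, RESPONDER, RESPONDER])
        res = choose_threshold(scores, labels)
        assert res.threshold == 0.0 and res.youden_j == 1.0 and res.accuracy == 1.0
        assert not res.degenerate

    def test_identical_scores_flagged_degenerate_lowest_cutoff(self):
        scores = np.full(6, 3.0)
        labels = two_group_labels(3, 3)
        res = choose_threshold(scores, labels)
        assert res.degenerate and res.youden_j == 0.0
        assert res.threshold == 2.0  # the below-minimum cutoff

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            choose_threshold(np.arange(4.0), np.array([RESPONDER] * 4))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_cutoff_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.normal(size=n).round(1)  # rounding forces ties
        labels = np.where(rng.random(n) < 0.5, RESPONDER, NON_RESPONDER)
        if len(set(labels)) < 2:
            labels[0], labels[-1] = RESPONDER, NON_RESPONDER
        res = choose_threshold(scores, labels)
        pos = labels == RESPONDER
        best_j = max(
            (scores > c).astype(int)[pos].mean() + (~(scores > c))[~pos].mean() - 1.0
            for c in np.concatenate([scores - 1e-9, scores + 1e-9])
        )
        assert np.isclose(res.youden_j, best_j)


class TestSerialization:
    def test_roundtrip_is_lossless(self, tmp_path):
        X, y = make_xy(17)
        model = PLSSignatureClassifier().fit(X, y, gene_ids=[f"G{i}" for i in range(6)])
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PLSSignatureClassifier.from_json(path)
        assert loaded.gene_ids_ == model.gene_ids_
        assert (loaded.weights_ == model.weights_).all()
        assert (loaded.center_ == model.center_).all()
        assert (loaded.scale_ == model.scale_).all()
        assert loaded.threshold_ == model.threshold_
        new = np.random.default_rng(0).normal(size=(5, 6))
        assert (loaded.decision_function(new) == model.decision_function(new)).all()

    def test_from_json_accepts_text(self):
        X, y = make_xy(18)
        model = PLSSignatureClassifier().fit(X, y)
        text = model.to_json()
        loaded = PLSSignatureClassifier.from_json(text)
        assert loaded.threshold_ == model.threshold_
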