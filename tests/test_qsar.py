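"""SIMPLS, kernel/tree/neighbour regressors, consensus, serialization."""

import numpy as np
import pytest

from fieldqsar import qsar
from fieldqsar.qsar import (ConsensusModel, consensus_predict, fit_regressor,
                            load_model_bundle, rvm_fit, save_model_bundle,
                            simpls_fit)


def _ols_fitted(X, y):
    Xc = X - X.mean(axis=0)
    beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    return Xc @ beta + y.mean()


class TestSimpls:
    @pytest.mark.parametrize("trial", range(10))
    def test_full_rank_equals_least_squares(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = simpls_fit(X, y, 5)
        assert np.abs(m.predict(X) - _ols_fitted(X, y)).max() < 1e-8

    @pytest.mark.parametrize("trial", range(5))
    def test_score_orthogonality(self, trial):
        rng = np.random.default_rng(100 + trial)
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        m = simpls_fit(X, y, 6)
        G = m.scores.T @ m.scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_coefficient_path_nesting(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        small = simpls_fit(X, y, 3)
        big = simpls_fit(X, y, 7)
        nested_coef = big.weights[:, :3] @ big.y_loadings[:3]
        assert np.allclose(small.coef, nested_coef, atol=1e-10)

    def test_univariate_collapses_to_ols_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(25, 1))
        y = 1.7 * x[:, 0] + rng.normal(size=25)
        m = simpls_fit(x, y, 1)
        slope = np.cov(x[:, 0], y)[0, 1] / np.var(x[:, 0], ddof=1)
        assert m.coef[0] == pytest.approx(slope, abs=1e-10)

    def test_constant_response(self):
        X = np.random.default_rng(3).normal(size=(15, 4))
        m = simpls_fit(X, np.full(15, 6.5), 2)
        assert np.all(m.coef == 0.0)
        assert m.intercept == pytest.approx(6.5)

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(4)
        X = np.tile(rng.normal(size=(20, 2)), (1, 3))  # rank 2
        with pytest.raises(ValueError, match="rank"):
            simpls_fit(X, rng.normal(size=20), 4)

    def test_predict_mean_row_gives_mean_response(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        m = simpls_fit(X, y, 3)
        assert m.predict(X.mean(axis=0))[0] == pytest.approx(y.mean(),
                                                             abs=1e-10)

    def test_prediction_affine_in_x(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        m = simpls_fit(X, y, 2)
        a, d = X[0], X[1] - X[0]
        base = m.predict(a)[0]
        step = m.predict(a + d)[0] - base
        assert m.predict(a + 2.0 * d)[0] == pytest.approx(base + 2.0 * step,
                                                          abs=1e-8)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        m = simpls_fit(rng.normal(size=(20, 4)), rng.normal(size=20), 2)
        with pytest.raises(ValueError, match="descriptor count"):
            m.predict(np.zeros((3, 5)))


class TestRvm:
    def test_sparsity_on_planted_bases(self):
        # response generated by 5 of 50 RBF kernel bases: the fitted RVM
        # must retain far fewer than all 50
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 2))
        from scipy.spatial.distance import cdist
        K = np.exp(-0.5 * cdist(X, X, "sqeuclidean"))
        w_true = np.zeros(50)
        w_true[rng.choice(50, 5, replace=False)] = rng.normal(size=5) * 3
        y = K @ w_true + 0.01 * rng.normal(size=50)
        m = rvm_fit(X, y, gamma=0.5)
        assert m.n_relevance_vectors < 50
        assert 1 - np.var(y - m.predict(X)) / np.var(y) > 0.95

    def test_noise_precision_positive(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=40)
        m = rvm_fit(X, y, gamma=0.3)
        assert m.beta > 0


class TestFitRegressor:
    def test_knn_k1_memorizes(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_regressor("knn", X, y,
                          grids={"knn": {"k": [1], "weights": ["uniform"]}})
        assert np.allclose(m.predict(X), y)

    def test_forest_prediction_is_mean_of_trees(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        m = fit_regressor("rf", X, y)
        Xs = (X - m.x_mean) / m.x_scale
        per_tree = np.stack([t.predict(Xs) for t in m.estimator.estimators_])
        assert np.allclose(per_tree.mean(axis=0), m.estimator.predict(Xs),
                           atol=1e-10)

    def test_knn_prediction_within_training_range(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        m = fit_regressor("knn", X, y)
        pred = m.predict(rng.normal(size=(10, 3)))
        assert pred.min() >= y.min() - 1e-12
        assert pred.max() <= y.max() + 1e-12

    def test_svm_recovers_noiseless_linear_signal(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(130, 5))
        y = X @ rng.normal(size=5)
        m = fit_regressor("svm", X[:100], y[:100])
        resid = y[100:] - m.predict(X[100:])
        r2 = 1 - np.var(resid) / np.var(y[100:])
        assert r2 >= 0.99

    def test_degenerate_response_constant_model(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(15, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_regressor("svm", X, np.full(15, 3.3))
        assert np.allclose(m.predict(X), 3.3)

    def test_chosen_params_reported(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        m = fit_regressor("svm", X, y)
        assert {"gamma", "C", "epsilon"} <= set(m.chosen_params)


class TestConsensus:
    class _Const:
        def __init__(self, v):
            self.v = v

        def predict(self, X):
            return np.full(len(np.atleast_2d(X)), self.v)

    def test_mean_of_members(self):
        X = np.zeros((4, 2))
        assert np.allclose(
            consensus_predict([self._Const(7.0), self._Const(9.0)], X), 8.0)
        assert np.allclose(
            consensus_predict([self._Const(8.0), self._Const(8.0)], X), 8.0)

    def test_single_member_identity(self):
        X = np.zeros((3, 2))
        assert np.allclose(consensus_predict([self._Const(5.5)], X), 5.5)

    def test_consensus_within_member_envelope(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + 0.2 * rng.normal(size=30)
        m1 = simpls_fit(X, y, 2)
        m2 = fit_regressor("knn", X, y)
        c = ConsensusModel([m1, m2], ["pls", "knn"])
        preds = np.stack([m1.predict(X), m2.predict(X)])
        cp = c.predict(X)
        assert np.all(cp >= preds.min(axis=0) - 1e-12)
        assert np.all(cp <= preds.max(axis=0) + 1e-12)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            consensus_predict([], np.zeros((2, 2)))


class TestSerialization:
    def test_bundle_round_trip_predicts_identically(self, tmp_path):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 5))
        y = X[:, 0] - X[:, 2] + 0.1 * rng.normal(size=40)
        models = {
            "field": simpls_fit(X, y, 3),
            "svm": fit_regressor("svm", X, y),
            "rvm": fit_regressor("rvm", X, y),
        }
        models["consensus"] = ConsensusModel(
            [models["field"], models["svm"]], ["field", "svm"])
        save_model_bundle(models, tmp_path / "bundle", training_hash="abc")
        back = load_model_bundle(tmp_path / "bundle")
        Xnew = rng.normal(size=(10, 5))
        for name in models:
            assert np.array_equal(models[name].predict(Xnew),
                                  back[name].predict(Xnew)), name
        assert (tmp_path / "bundle" / "MODEL_CARD.md").exists()
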