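"""Regression models for field-descriptor QSAR.

The field model is partial least squares fitted with the SIMPLS algorithm
(de Jong 1993): components are extracted by successive rank-one deflation
of the predictor-response cross-product s = X'y, each new weight vector
being projected onto the orthocomplement of the previous loadings, which
yields mutually orthogonal score vectors t_a = X r_a.

The machine-learning models (epsilon-SVR and k-nearest-neighbours and
random-forest regression) are standard estimators with hyperparameters
chosen by an inner cross-validated grid search on fixed, documented grids.
The relevance vector machine is a sparse Bayesian linear regression over an
RBF kernel basis with evidence (type-II maximum likelihood) optimization,
implemented here because no mainstream dependency ships one.

The consensus predictor averages the field-PLS and SVR predictions
(unweighted by default; weights are configurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

__all__ = [
    "PLSModel", "simpls_fit", "RVMModel", "rvm_fit", "SklearnModel",
    "fit_regressor", "ConsensusModel", "consensus_predict",
    "save_model_bundle", "load_model_bundle", "DEFAULT_GRIDS",
]


# --------------------------------------------------------------------------
# SIMPLS partial least squares
# --------------------------------------------------------------------------

@dataclass
class PLSModel:
    """SIMPLS partial-least-squares regression of pKi on descriptors.

    Predictors are mean-centered only (no variance scaling); the response is
    mean-centered. ``coef``/``intercept`` are on the original scale so that
    prediction is simply ``X @ coef + intercept``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # R (p, A): X-weights, t_a = Xc @ R[:, a]
    loadings: np.ndarray   # P (p, A)
    y_loadings: np.ndarray  # q (A,)
    scores: np.ndarray     # T (n, A), training scores
    coef: np.ndarray       # (p,)
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"descriptor count {X.shape[1]} != training {self.coef.shape[0]}")
        return X @ self.coef + self.intercept


def simpls_fit(X: np.ndarray, y: np.ndarray, n_components: int = 5) -> PLSModel:
    """Fit PLS regression with the SIMPLS algorithm.

    Parameters
    ----------
    X : (n, p) descriptor matrix; y : (n,) response; n_components : A >= 1.

    Notes
    -----
    Deterministic. Component a maximizes covariance of the score t = Xc r
    with the centered response subject to orthogonality of t to all earlier
    scores, achieved by deflating s = Xc' yc against an orthonormal basis of
    the earlier loading vectors. Raises when A exceeds the rank of the
    centered X. The coefficient path is nested: the first A' < A components
    of a larger fit equal the smaller fit exactly.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    A = int(n_components)
    if A < 1:
        raise ValueError("n_components must be >= 1")
    if n < A + 2:
        raise ValueError(f"need n >= A+2 rows, got n={n}, A={A}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    rank = np.linalg.matrix_rank(Xc)
    if np.allclose(yc, 0.0):
        # constant response: zero coefficients, intercept = mean
        zero = np.zeros(p)
        return PLSModel(A, x_mean, y_mean,
                        weights=np.zeros((p, A)), loadings=np.zeros((p, A)),
                        y_loadings=np.zeros(A), scores=np.zeros((n, A)),
                        coef=zero, intercept=y_mean)
    if A > rank:
        raise ValueError(f"n_components={A} exceeds achievable rank {rank}")

    s = Xc.T @ yc
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    T = np.zeros((n, A))
    V = np.zeros((p, A))   # orthonormal basis of loadings
    for a in range(A):
        r = s.copy()
        t = Xc @ r
        t_norm = np.linalg.norm(t)
        if t_norm < 1e-12:
            raise ValueError(f"component {a + 1} degenerate; achievable rank "
                             f"is {a}")
        t /= t_norm
        r /= t_norm
        pvec = Xc.T @ t
        q = float(yc @ t)
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R[:, a], P[:, a], Q[a], T[:, a], V[:, a] = r, pvec, q, t, v
    coef = R @ Q
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(A, x_mean, y_mean, R, P, Q, T, coef, intercept)


# --------------------------------------------------------------------------
# Relevance vector machine (sparse Bayesian RBF regression)
# --------------------------------------------------------------------------

@dataclass
class RVMModel:
    """Sparse Bayesian regression over an RBF kernel basis plus bias.

    Basis functions are k(x, x_m) = exp(-gamma ||x - x_m||^2) centered on
    the retained (relevant) training vectors. ``alpha`` are the retained
    weight precisions, ``beta`` the noise precision.
    """

    gamma: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    relevance_vectors: np.ndarray    # (m, p) in scaled space
    weights: np.ndarray              # (m + 1,), [bias, w_1..w_m]
    alpha: np.ndarray
    beta: float

    def _design(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        K = np.exp(-self.gamma * cdist(Xs, self.relevance_vectors,
                                       "sqeuclidean"))
        return np.hstack([np.ones((len(Xs), 1)), K])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._design(X) @ self.weights

    @property
    def n_relevance_vectors(self) -> int:
        return len(self.relevance_vectors)


def _rvm_evidence_fit(Phi: np.ndarray, y: np.ndarray, max_iter: int = 1000,
                      tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, float]:
    """Evidence maximization for linear-in-basis Bayesian regression.

    Iterates the standard alpha_i <- gamma_i / mu_i^2 and beta updates,
    pruning bases whose precision diverges (alpha > 1e9). Returns
    (active basis indices, posterior mean weights on them, beta).
    """
    n, m = Phi.shape
    active = np.arange(m)
    alpha = np.full(m, 1e-3)
    beta = 1.0 / max(np.var(y) * 0.1, 1e-6)
    mu = np.zeros(m)
    last_logev = -np.inf
    for _ in range(max_iter):
        Pa = Phi[:, active]
        A = np.diag(alpha[active])
        H = beta * Pa.T @ Pa + A
        # posterior over active weights
        L = np.linalg.cholesky(H)
        Sigma = np.linalg.inv(H)
        mu_a = beta * Sigma @ (Pa.T @ y)
        gamma_i = 1.0 - alpha[active] * np.diag(Sigma)
        # updates
        new_alpha = alpha.copy()
        with np.errstate(divide="ignore"):
            new_alpha[active] = gamma_i / np.maximum(mu_a ** 2, 1e-300)
        resid = y - Pa @ mu_a
        beta = (n - gamma_i.sum()) / max(float(resid @ resid), 1e-12)
        alpha = new_alpha
        keep = alpha[active] < 1e9
        active = active[keep]
        if len(active) == 0:
            # all bases pruned: constant model via the first basis (bias)
            active = np.array([0])
            alpha[0] = 1e-6
            continue
        mu = np.zeros(m)
        mu[active] = mu_a[keep]
        # log evidence for convergence check
        logev = (0.5 * np.log(alpha[active]).sum()
                 + 0.5 * n * np.log(beta)
                 - 0.5 * beta * float(resid @ resid)
                 - 0.5 * float((alpha[active] * mu[active] ** 2).sum())
                 - np.log(np.diag(L)).sum())
        if abs(logev - last_logev) < tol:
            break
        last_logev = logev
    return active, mu[active], beta


def _center_global_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and a single global scale (overall descriptor sd).

    Kernel and neighbour models use centered descriptors divided by one
    global factor rather than per-column autoscaling: unit-variance scaling
    would inflate near-constant, noise-dominated field columns until they
    dominate every distance, while a global scale preserves the natural
    covariance structure of the molecular fields.
    """
    x_mean = X.mean(axis=0)
    g = float(X.std())
    if g < 1e-12:
        g = 1.0
    return x_mean, np.full(X.shape[1], g)


def rvm_fit(X: np.ndarray, y: np.ndarray, gamma: float,
            max_iter: int = 1000, tol: float = 1e-6) -> RVMModel:
    """Fit the RVM on centered, globally scaled descriptors with an RBF basis."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean, x_scale = _center_global_scale(X)
    Xs = (X - x_mean) / x_scale
    K = np.exp(-gamma * cdist(Xs, Xs, "sqeuclidean"))
    Phi = np.hstack([np.ones((len(Xs), 1)), K])
    active, w_active, beta = _rvm_evidence_fit(Phi, y, max_iter, tol)
    has_bias = 0 in active
    kernel_idx = np.array([i - 1 for i in active if i != 0], dtype=int)
    weights = np.empty(len(kernel_idx) + 1)
    weights[0] = w_active[list(active).index(0)] if has_bias else 0.0
    weights[1:] = [w_active[list(active).index(i + 1)] for i in kernel_idx]
    alpha_out = np.array([0.0] + [0.0] * len(kernel_idx))
    return RVMModel(gamma, x_mean, x_scale, Xs[kernel_idx], weights,
                    alpha_out, beta)


# --------------------------------------------------------------------------
# Grid-searched standard regressors
# --------------------------------------------------------------------------

# Kernel widths are multiples of the dimension-aware scale
# 1 / (n_features * var(X_standardized)), so the same grid works for tens or
# thousands of descriptor columns.
DEFAULT_GRIDS = {
    "svm": {"gamma_rel": [2.0 ** k for k in (-10, -8, -6, -4, -2)],
            "C": [2.0 ** k for k in (0, 2, 4, 6, 8, 10)],
            "epsilon": [0.1, 0.2]},
    "knn": {"k": list(range(1, 16)), "weights": ["uniform", "distance"]},
    "rf": {"n_trees": [200], "max_depth": [None, 8]},
    "rvm": {"gamma_rel": [2.0 ** k for k in (-6, -4, -2, 0)]},
}


@dataclass
class SklearnModel:
    """A fitted standard regressor plus the standardization it was fit with."""

    kind: str
    estimator: object
    x_mean: np.ndarray
    x_scale: np.ndarray
    chosen_params: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        return np.asarray(self.estimator.predict(Xs), float)


class _ConstantModel:
    """Degenerate-response fallback: predicts the training mean."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.value)


def _cv_mse_svr(D2, y, folds, gamma, C, epsilon):
    K = np.exp(-gamma * D2)
    err = 0.0
    for tr, te in folds:
        est = SVR(kernel="precomputed", C=C, epsilon=epsilon)
        est.fit(K[np.ix_(tr, tr)], y[tr])
        pred = est.predict(K[np.ix_(te, tr)])
        err += float(((pred - y[te]) ** 2).sum())
    return err / len(y)


def fit_regressor(kind: str, X: np.ndarray, y: np.ndarray,
                  cv_folds: int = 3, seed: int = 2021,
                  grids: dict | None = None):
    """Fit one of the supervised models with inner-CV hyperparameter search.

    ``kind`` is one of svm / knn / rf / rvm. Descriptors are centered and
    divided by a single global scale before kernel and neighbour models
    (see :func:`_center_global_scale`). Grids are fixed and documented in
    :data:`DEFAULT_GRIDS`; the chosen values are recorded on the returned
    model. A zero-variance response yields a constant model.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if len(y) < 10:
        raise ValueError("need n >= 10 samples")
    grid = (grids or DEFAULT_GRIDS)[kind]
    x_mean, x_scale = _center_global_scale(X)
    Xs = (X - x_mean) / x_scale
    if np.var(y) < 1e-12:
        import warnings
        warnings.warn(f"{kind}: zero-variance response; constant model")
        return SklearnModel(kind, _ConstantModel(y.mean()), x_mean, x_scale,
                            {"constant": True})
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(Xs))

    gamma_scale = 1.0 / (Xs.shape[1] * max(float(Xs.var()), 1e-12))

    if kind == "svm":
        best = None
        D2 = cdist(Xs, Xs, "sqeuclidean")
        for gamma in [g * gamma_scale for g in grid["gamma_rel"]]:
            for C in grid["C"]:
                for eps in grid["epsilon"]:
                    mse = _cv_mse_svr(D2, y, folds, gamma, C, eps)
                    key = (mse, gamma, C, eps)
                    if best is None or key < best:
                        best = key
        _, gamma, C, eps = best
        est = SVR(kernel="rbf", gamma=gamma, C=C, epsilon=eps)
        est.fit(Xs, y)
        return SklearnModel(kind, est, x_mean, x_scale,
                            {"gamma": gamma, "C": C, "epsilon": eps})

    if kind == "knn":
        best = None
        for k in grid["k"]:
            if k >= len(y) * (cv_folds - 1) // cv_folds:
                continue
            for w in grid["weights"]:
                mse = 0.0
                for tr, te in folds:
                    est = KNeighborsRegressor(n_neighbors=min(k, len(tr)),
                                              weights=w)
                    est.fit(Xs[tr], y[tr])
                    mse += float(((est.predict(Xs[te]) - y[te]) ** 2).sum())
                key = (mse / len(y), k, w)
                if best is None or key < best:
                    best = key
        _, k, w = best
        est = KNeighborsRegressor(n_neighbors=k, weights=w)
        est.fit(Xs, y)
        return SklearnModel(kind, est, x_mean, x_scale,
                            {"k": k, "weights": w})

    if kind == "rf":
        best = None
        for nt in grid["n_trees"]:
            for depth in grid["max_depth"]:
                mse = 0.0
                for tr, te in folds:
                    est = RandomForestRegressor(
                        n_estimators=max(50, nt // 4), max_depth=depth,
                        random_state=seed, n_jobs=1)
                    est.fit(Xs[tr], y[tr])
                    mse += float(((est.predict(Xs[te]) - y[te]) ** 2).sum())
                key = (mse / len(y), nt, -1 if depth is None else depth)
                if best is None or key < best[0]:
                    best = (key, nt, depth)
        _, nt, depth = best
        est = RandomForestRegressor(n_estimators=nt, max_depth=depth,
                                    random_state=seed, n_jobs=1)
        est.fit(Xs, y)
        return SklearnModel(kind, est, x_mean, x_scale,
                            {"n_trees": nt, "max_depth": depth})

    if kind == "rvm":
        best = None
        for gamma in [g * gamma_scale for g in grid["gamma_rel"]]:
            mse = 0.0
            for tr, te in folds:
                m = rvm_fit(X[tr], y[tr], gamma=gamma, max_iter=200)
                mse += float(((m.predict(X[te]) - y[te]) ** 2).sum())
            key = (mse / len(y), gamma)
            if best is None or key < best:
                best = key
        _, gamma = best
        return rvm_fit(X, y, gamma=gamma)

    raise ValueError(f"unknown model kind {kind!r}")


# --------------------------------------------------------------------------
# Consensus
# --------------------------------------------------------------------------

@dataclass
class ConsensusModel:
    """Weighted-mean combination of member predictions (unweighted default).

    The default member pair mirrors the pipeline's strongest models: the
    field PLS and the SVR. The consensus prediction always lies inside the
    [min, max] envelope of the member predictions.
    """

    members: list
    member_names: list[str]
    weights: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([np.asarray(m.predict(X), float)
                          for m in self.members])
        if self.weights is None:
            return preds.mean(axis=0)
        w = np.asarray(self.weights, float)
        return (w[:, None] * preds).sum(axis=0) / w.sum()


def consensus_predict(members: Sequence, X: np.ndarray,
                      weights: Sequence[float] | None = None) -> np.ndarray:
    """Mean (optionally weighted) of member predictions per row."""
    if not members:
        raise ValueError("need at least one member model")
    model = ConsensusModel(list(members), [type(m).__name__ for m in members],
                           None if weights is None else np.asarray(weights))
    return model.predict(X)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_model_bundle(models: dict, path: str | Path, stats: dict | None = None,
                      training_hash: str = "") -> None:
    """Persist fitted models to a directory with a JSON manifest + model card."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"models": {}, "training_hash": training_hash}
    for name, model in models.items():
        fn = f"{name}.joblib"
        joblib.dump(model, path / fn)
        params = getattr(model, "chosen_params", None)
        if isinstance(model, PLSModel):
            params = {"n_components": model.n_components}
        elif isinstance(model, RVMModel):
            params = {"gamma": model.gamma,
                      "n_relevance_vectors": model.n_relevance_vectors}
        manifest["models"][name] = {"file": fn, "params": params}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    card = ["# Model card", "", f"Training hash: {training_hash or 'n/a'}", ""]
    for name, meta in manifest["models"].items():
        card.append(f"- **{name}**: {meta['params']}")
    if stats:
        card += ["", "## Statistics", "", "```json",
                 json.dumps(stats, indent=2, default=float), "```"]
    (path / "MODEL_CARD.md").write_text("\n".join(card) + "\n")


def load_model_bundle(path: str | Path) -> dict:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return {name: joblib.load(path / meta["file"])
            for name, meta in manifest["models"].items()}
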