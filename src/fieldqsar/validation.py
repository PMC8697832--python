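"""Activity-stratified splitting, cross-validation, and model statistics.

The statistics panel mirrors standard QSAR reporting: r^2 (coefficient of
determination) and LOO-cross-validated q^2 on the training set, r^2 on the
held-out test set (both the coefficient of determination about the test
mean and the squared Pearson correlation are reported, since the two are
often conflated), plus MSE, MAE and MAPE for train and test. A ranking
diagnostic regresses experimental log-potencies on predicted pKi and checks
top/bottom overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import math
import numpy as np
from scipy import stats as sps

__all__ = [
    "SplitSpec", "stratified_split", "r2", "pearson_r2", "mse", "mae", "mape",
    "q2_loo", "q2_kfold", "ModelStats", "evaluate_all", "ranking_fit",
    "RankingFit",
]


@dataclass(frozen=True)
class SplitSpec:
    """Activity-stratified train/test split parameters."""

    train_fraction: float = 0.8
    n_strata: int = 10
    seed: int = 2021

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")


def stratified_split(ids: Sequence[str], pki: Sequence[float],
                     spec: SplitSpec | None = None
                     ) -> tuple[list[str], list[str]]:
    """Split ids into train/test stratified on activity.

    Records are sorted by pKi, partitioned into ``n_strata`` equal-frequency
    bins, and the train fraction is sampled within each bin with the spec's
    seed. The total train size is exactly round(fraction * n), apportioned
    to bins by largest remainder so both partitions span the activity range.
    """
    spec = spec or SplitSpec()
    ids = list(ids)
    y = np.asarray(pki, float)
    n = len(ids)
    if len(set(ids)) != n:
        raise ValueError("duplicate ids in split input")
    if n < 2 * spec.n_strata:
        raise ValueError(f"need n >= 2 * n_strata = {2 * spec.n_strata}")
    n_train_total = round(spec.train_fraction * n)

    order = np.lexsort((np.arange(n), y))  # stable in id order for ties
    bins = np.array_split(order, spec.n_strata)

    # largest-remainder apportionment of the train quota across bins
    quotas = np.array([spec.train_fraction * len(b) for b in bins])
    base = np.floor(quotas).astype(int)
    short = n_train_total - base.sum()
    remainder_order = np.argsort(-(quotas - base), kind="stable")
    counts = base.copy()
    for j in remainder_order[:short]:
        counts[j] += 1
    counts = np.minimum(counts, [len(b) for b in bins])

    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    for b, c in zip(bins, counts):
        chosen = rng.choice(len(b), size=c, replace=False)
        train_idx.extend(b[sorted(chosen)])
    train_set = set(train_idx)
    train = [ids[i] for i in range(n) if i in train_set]
    test = [ids[i] for i in range(n) if i not in train_set]
    return train, test


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------

def _check(y, yhat):
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("y and yhat must be equal-length and non-empty")
    return y, yhat


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SSres/SStot (about the mean of y)."""
    y, yhat = _check(y, yhat)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("r2 undefined for zero-variance y")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def pearson_r2(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y, yhat = _check(y, yhat)
    if np.var(y) <= 0 or np.var(yhat) <= 0:
        raise ValueError("pearson_r2 undefined for a constant vector")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def mse(y, yhat) -> float:
    """Mean squared forecast error."""
    y, yhat = _check(y, yhat)
    return float(((y - yhat) ** 2).mean())


def mae(y, yhat) -> float:
    """Mean absolute forecast error."""
    y, yhat = _check(y, yhat)
    return float(np.abs(y - yhat).mean())


def mape(y, yhat) -> float:
    """Mean absolute percentage forecast error, in percent."""
    y, yhat = _check(y, yhat)
    if np.any(y == 0):
        raise ValueError("mape undefined when some y == 0")
    return float(100.0 * (np.abs(y - yhat) / np.abs(y)).mean())


def q2_loo(model_factory: Callable, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cross-validated q^2 = 1 - PRESS/SStot.

    ``model_factory(X, y)`` must return a fitted object with ``predict``.
    Each sample is predicted by a model trained on the remaining n-1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 5:
        raise ValueError("need n >= 5 for LOO q2")
    press = 0.0
    mask = np.ones(n, bool)
    for i in range(n):
        mask[i] = False
        try:
            model = model_factory(X[mask], y[mask])
        except Exception as exc:
            raise RuntimeError(f"LOO fold {i} failed: {exc}") from exc
        pred = float(np.asarray(model.predict(X[i][None, :])).ravel()[0])
        press += (y[i] - pred) ** 2
        mask[i] = True
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def q2_kfold(model_factory: Callable, X: np.ndarray, y: np.ndarray,
             k: int = 5, seed: int = 2021) -> float:
    """k-fold analogue of :func:`q2_loo` (labelled distinctly in reports)."""
    from sklearn.model_selection import KFold
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    press = 0.0
    for tr, te in KFold(k, shuffle=True, random_state=seed).split(X):
        model = model_factory(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te])).ravel()
        press += float(((y[te] - pred) ** 2).sum())
    return 1.0 - press / float(((y - y.mean()) ** 2).sum())


@dataclass
class ModelStats:
    """One model's row of the statistics panel."""

    name: str
    r2_train: float
    q2_train: float | None
    r2_test: float
    pearson_r2_test: float
    mse_train: float
    mse_test: float
    mae_train: float
    mae_test: float
    mape_train: float
    mape_test: float

    def __post_init__(self):
        for field_name in ("mse_train", "mse_test", "mae_train", "mae_test",
                           "mape_train", "mape_test"):
            v = getattr(self, field_name)
            if v < 0:
                raise ValueError(f"{field_name} must be >= 0")
        # Jensen: mean|e| <= sqrt(mean e^2)
        assert self.mae_train <= math.sqrt(self.mse_train) + 1e-12
        assert self.mae_test <= math.sqrt(self.mse_test) + 1e-12


def evaluate_all(
    models: dict,
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray,
    q2_factories: dict | None = None,
) -> list[ModelStats]:
    """Statistics panel for a set of fitted models sharing a descriptor space.

    ``q2_factories`` optionally maps model names to refit factories for the
    cross-validated q^2 column; models without one get q2 = None.
    """
    rows = []
    for name, model in models.items():
        pred_tr = np.asarray(model.predict(X_train), float).ravel()
        pred_te = np.asarray(model.predict(X_test), float).ravel()
        q2 = None
        if q2_factories and name in q2_factories:
            q2 = q2_loo(q2_factories[name], X_train, y_train)
        rows.append(ModelStats(
            name=name,
            r2_train=r2(y_train, pred_tr),
            q2_train=q2,
            r2_test=r2(y_test, pred_te),
            pearson_r2_test=pearson_r2(y_test, pred_te),
            mse_train=mse(y_train, pred_tr),
            mse_test=mse(y_test, pred_te),
            mae_train=mae(y_train, pred_tr),
            mae_test=mae(y_test, pred_te),
            mape_train=mape(y_train, pred_tr),
            mape_test=mape(y_test, pred_te),
        ))
    return rows


def write_stats_tsv(rows: Sequence[ModelStats], path: str | Path) -> None:
    """Write the panel as TSV, one model per row."""
    cols = ["model", "r2_train", "q2_train", "r2_test", "pearson_r2_test",
            "mse_train", "mse_test", "mae_train", "mae_test",
            "mape_train", "mape_test"]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r_ in rows:
            vals = [r_.name] + [
                "" if getattr(r_, c) is None else f"{getattr(r_, c):.4f}"
                for c in cols[1:]]
            fh.write("\t".join(vals) + "\n")


# --------------------------------------------------------------------------
# Ranking diagnostic
# --------------------------------------------------------------------------

@dataclass
class RankingFit:
    slope: float
    intercept: float
    r2: float
    top_overlap: int
    bottom_overlap: int
    m: int


def ranking_fit(predicted_pki: Sequence[float],
                experimental_potency: Sequence[float],
                log_transform: bool = True, m: int = 5) -> RankingFit:
    """OLS of experimental (log-transformed) potency on predicted pKi.

    ``experimental_potency`` values are typically EC50/IC50 concentrations;
    with ``log_transform`` they are converted to -log10 before the fit so
    higher = more potent on both axes. Also reports how many of the top-m
    (and bottom-m) experimental compounds the predictions place in their
    own top-m (bottom-m) — the potent/weak classification check.
    """
    pred = np.asarray(predicted_pki, float).ravel()
    pot = np.asarray(experimental_potency, float).ravel()
    if len(pred) != len(pot) or len(pred) < 3:
        raise ValueError("need >= 3 matched pairs")
    if log_transform:
        if np.any(pot <= 0):
            raise ValueError("non-positive potency cannot be log-transformed")
        exp_val = -np.log10(pot)
    else:
        exp_val = pot
    res = sps.linregress(pred, exp_val)
    m_eff = min(m, len(pred) // 2)
    top_exp = set(np.argsort(-exp_val, kind="stable")[:m_eff])
    top_pred = set(np.argsort(-pred, kind="stable")[:m_eff])
    bot_exp = set(np.argsort(exp_val, kind="stable")[:m_eff])
    bot_pred = set(np.argsort(pred, kind="stable")[:m_eff])
    return RankingFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        top_overlap=len(top_exp & top_pred),
        bottom_overlap=len(bot_exp & bot_pred),
        m=m_eff,
    )
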