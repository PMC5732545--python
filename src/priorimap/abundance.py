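"""Abundance modelling: stepwise predictor selection, the random-forest
count regressor, validation metrics, and the linear abundance adjustment.

The abundance model regresses flock counts at presence sites on the
habitat predictors. Because tree regressors compress the response range
(they regress extremes toward the mean), the raw per-pixel prediction
("prediction abundance", RA) is re-calibrated against the observed counts
with an ordinary least-squares line::

    adjusted abundance = A × prediction abundance + B

fitted from (prediction, observation) pairs; the adjusted surface is
clipped at zero since counts cannot be negative.

R² here is the squared Pearson correlation between observed and predicted
values (``method="pearson"``); the ``1 − SSE/SST`` variant is available
via ``method="sse"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .grid import Grid
from .layers import PredictorStack

_PREDICT_CHUNK = 200_000


# ---------------------------------------------------------------------------
# metrics


def rmse(obs, pred) -> float:
    """Root mean squared error, in the units of the response."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("obs and pred must have equal nonzero length")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(obs, pred, method: str = "pearson") -> float:
    """Coefficient of determination between observed and predicted.

    ``"pearson"`` (default): squared Pearson correlation, the symmetric
    agreement measure used for observed-vs-predicted scatter;
    ``"sse"``: 1 − SSE/SST (can be negative for poor predictions).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("obs and pred must have equal length >= 3")
    if method == "pearson":
        if obs.std() == 0 or pred.std() == 0:
            raise ValueError("zero variance in obs or pred")
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r * r)
    if method == "sse":
        sst = np.sum((obs - obs.mean()) ** 2)
        if sst == 0:
            raise ValueError("zero variance in obs")
        return float(1.0 - np.sum((obs - pred) ** 2) / sst)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(samples: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive split; train size = round(f·n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = samples.iloc[perm[:n_train]].reset_index(drop=True)
    test = samples.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


# ---------------------------------------------------------------------------
# the regressor


class AbundanceModel(BaseEstimator, RegressorMixin):
    """Random-forest count regressor with OOB predictions.

    Attributes (after ``fit``)
    --------------------------
    regressor_ : RandomForestRegressor
    feature_names_ : list of str — the selected predictors
    oob_predictions_ : ndarray — per-training-point OOB prediction
    oob_rmse_ : float
    oob_r_squared_ : float — squared Pearson corr. of obs vs OOB pred
    importances_ : list of (name, score), descending
    """

    def __init__(self, n_trees: int = 1000, feature_names=None, seed: int = 0):
        self.n_trees = n_trees
        self.feature_names = feature_names
        self.seed = seed

    def fit(self, X, y):
        X, names = _as_matrix(X, self.feature_names)
        y = np.asarray(y, dtype=float)
        if X.shape[1] < 1:
            raise ValueError("need at least one predictor")
        if np.all(y == y[0]):
            raise ValueError("constant response; nothing to regress")
        reg = RandomForestRegressor(
            n_estimators=self.n_trees,
            oob_score=True,
            bootstrap=True,
            n_jobs=1,
            random_state=self.seed,
        )
        reg.fit(X, y)
        oob = reg.oob_prediction_
        if np.isnan(oob).any():
            raise RuntimeError("OOB prediction undefined for some points; grow more trees")
        self.regressor_ = reg
        self.feature_names_ = list(names)
        self.oob_predictions_ = oob
        self.oob_rmse_ = rmse(y, oob)
        try:
            self.oob_r_squared_ = r_squared(y, oob)
        except ValueError:  # degenerate OOB predictions
            self.oob_r_squared_ = 0.0
        order = np.argsort(reg.feature_importances_)[::-1]
        self.importances_ = [(names[i], float(reg.feature_importances_[i])) for i in order]
        return self

    def predict_mean(self, X) -> np.ndarray:
        """Ensemble mean prediction (raw, may exceed observed range ends)."""
        check_is_fitted(self, "regressor_")
        X, _ = _as_matrix(X, self.feature_names_)
        return self.regressor_.predict(X)

    predict = predict_mean

    def save(self, model_dir: str | Path) -> Path:
        check_is_fitted(self, "regressor_")
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, model_dir / "abundance_model.joblib")
        meta = {
            "kind": "abundance",
            "n_trees": self.n_trees,
            "seed": self.seed,
            "feature_names": self.feature_names_,
            "oob_rmse": self.oob_rmse_,
            "oob_r_squared": self.oob_r_squared_,
        }
        (model_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        return model_dir

    @staticmethod
    def load(model_dir: str | Path) -> "AbundanceModel":
        return joblib.load(Path(model_dir) / "abundance_model.joblib")


def _as_matrix(X, feature_names):
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            from .layers import PREDICTOR_NAMES

            feature_names = [c for c in PREDICTOR_NAMES if c in X.columns]
            if not feature_names:
                feature_names = [
                    c for c in X.columns
                    if c not in ("point_id", "x", "y", "presence", "count", "provenance")
                ]
        return X[list(feature_names)].to_numpy(dtype=float), list(feature_names)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


def stepwise_select(samples: pd.DataFrame, candidates: Sequence[str],
                    n_trees: int = 500, seed: int = 0,
                    tol: float = 1e-3) -> list[str]:
    """Greedy forward predictor selection by out-of-bag R².

    Starting from the empty set, each step refits the regressor with each
    remaining candidate added and keeps the one with the highest OOB R²;
    selection stops when the best improvement over the current score falls
    below ``tol``. Ties break by candidate order. Deterministic per seed.
    """
    if not candidates:
        raise ValueError("no candidate predictors")
    y = samples["count"].to_numpy(dtype=float)
    selected: list[str] = []
    remaining = list(candidates)
    best_score = 0.0
    while remaining:
        step_best = None
        step_score = -np.inf
        for cand in remaining:
            model = AbundanceModel(n_trees=n_trees,
                                   feature_names=selected + [cand], seed=seed)
            model.fit(samples, y)
            score = model.oob_r_squared_
            if score > step_score:  # strict: ties keep earlier candidate
                step_best, step_score = cand, score
        if step_best is None or step_score - best_score < tol:
            break
        selected.append(step_best)
        remaining.remove(step_best)
        best_score = step_score
    return selected


def fit_abundance(samples: pd.DataFrame, selected: Sequence[str],
                  n_trees: int = 1000, seed: int = 0) -> AbundanceModel:
    """Fit the final abundance model on the selected predictors."""
    if not selected:
        raise ValueError("empty predictor selection")
    model = AbundanceModel(n_trees=n_trees, feature_names=list(selected), seed=seed)
    return model.fit(samples, samples["count"].to_numpy(dtype=float))


def predict_abundance(model: AbundanceModel, stack: PredictorStack) -> Grid:
    """Raw per-pixel prediction abundance (RA) surface; nodata propagated.

    No clipping here — non-negativity is enforced only after the linear
    adjustment.
    """
    check_is_fitted(model, "regressor_")
    missing = [n for n in model.feature_names_ if n not in stack]
    if missing:
        raise ValueError(f"stack missing predictor layers: {missing}")
    X, valid = stack.as_matrix(model.feature_names_)
    out = np.full(stack.template.shape, np.nan)
    flat = np.empty(X.shape[0])
    for start in range(0, X.shape[0], _PREDICT_CHUNK):
        block = slice(start, start + _PREDICT_CHUNK)
        flat[block] = model.predict_mean(X[block])
    out[valid] = flat
    return stack.template.copy_with(out, nodata=~valid)


# ---------------------------------------------------------------------------
# the linear adjustment


@dataclass
class AdjustmentFit:
    """OLS calibration of observed counts on predicted abundance."""

    A: float  # slope, unitless
    B: float  # intercept, count units
    r_squared: float

    def __call__(self, pred: np.ndarray) -> np.ndarray:
        return self.A * np.asarray(pred, dtype=float) + self.B


class AbundanceAdjustment(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper of the OLS adjustment: fit(pred, obs)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        fit = fit_adjustment(y, X)
        self.A_ = fit.A
        self.B_ = fit.B
        self.r_squared_ = fit.r_squared
        return self

    def predict(self, X):
        check_is_fitted(self, "A_")
        return self.A_ * np.asarray(X, dtype=float).ravel() + self.B_


def fit_adjustment(obs, pred) -> AdjustmentFit:
    """Ordinary least squares of observed counts on predictions.

    Returns slope A, intercept B, and the R² of the regression (squared
    Pearson correlation — identical to the OLS R² in simple regression).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need >= 3 (obs, pred) pairs")
    if np.std(pred) == 0:
        raise ValueError("predictions have zero variance; adjustment undefined")
    if np.std(obs) == 0:
        # constant observations: zero slope, intercept at the constant;
        # Pearson r is undefined, report 0
        return AdjustmentFit(A=0.0, B=float(obs[0]), r_squared=0.0)
    res = stats.linregress(pred, obs)
    return AdjustmentFit(A=float(res.slope), B=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def apply_adjustment(fit: AdjustmentFit, ra: Grid) -> Grid:
    """Pixel-wise ``A·RA + B`` clipped at zero; nodata propagated."""
    if not (np.isfinite(fit.A) and np.isfinite(fit.B)):
        raise ValueError("adjustment coefficients must be finite")
    vals = np.clip(fit.A * ra.values + fit.B, 0.0, None)
    vals = np.where(ra.nodata, np.nan, vals)
    return ra.copy_with(vals)
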