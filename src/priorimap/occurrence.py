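"""Occurrence modelling: pseudo-absence sampling, the random-forest
presence/background classifier, RIO prediction and diagnostics.

The relative index of occurrence (RIO) at a pixel is the fraction of
trees in the ensemble that vote for the presence class — a relative
suitability index in [0, 1], deliberately not a calibrated probability.
Class imbalance between the handful of presence sites and the thousands
of random background points is countered with balanced class weights
``w_c = N / (2 N_c)``.

Internal validation is out-of-bag (OOB): each training point is scored
only by the trees whose bootstrap sample did not contain it, and the ROC
AUC of those scores is the occurrence model's performance metric.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .grid import Grid
from .layers import PredictorStack, PREDICTOR_NAMES
from .observations import ObservationSet

_PREDICT_CHUNK = 200_000  # pixels per prediction block


def sample_pseudo_absences(study_mask: Grid, n: int, seed: int) -> ObservationSet:
    """Draw exactly ``n`` background points at distinct valid pixel centres.

    Uniform sampling without replacement over valid pixels of the study
    mask; presences are *not* excluded, mirroring plain random background
    sampling (collisions are vanishingly rare at study scale).
    """
    valid = study_mask.valid & (study_mask.values > 0)
    flat_idx = np.flatnonzero(valid.ravel())
    if flat_idx.size == 0:
        raise ValueError("study mask has no valid pixels")
    if n > flat_idx.size:
        raise ValueError(f"n={n} exceeds {flat_idx.size} valid pixels")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, study_mask.shape)
    x, y = study_mask.center_of(rows, cols)
    return ObservationSet(
        x=x,
        y=y,
        count=np.zeros(n, dtype=int),
        presence=np.zeros(n, dtype=int),
        provenance="pseudo-absence",
    )


def roc_auc(labels, scores) -> float:
    """ROC AUC: probability a random positive outscores a random negative,
    ties counted one half (Mann–Whitney rank formulation)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks -> ties counted 1/2
    rank_sum = ranks[pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


class OccurrenceModel(BaseEstimator, ClassifierMixin):
    """Random-forest presence/background classifier with OOB diagnostics.

    Parameters
    ----------
    n_trees : int, default 1000
        Number of classification trees.
    balanced : bool, default True
        Use balanced class weights ``w_c = N / (2 N_c)``.
    feature_names : sequence of str, optional
        Predictor columns used when fitting from a sample-matrix frame;
        defaults to the canonical 11-layer names present in the data.
    seed : int, default 0
        Random state of the ensemble.

    Attributes (after ``fit``)
    --------------------------
    classifier_ : RandomForestClassifier
    feature_names_ : list of str
    oob_scores_ : ndarray — per-training-point OOB presence score
    oob_roc_auc_ : float — ROC AUC of the OOB scores
    importances_ : list of (name, score), descending
    """

    def __init__(self, n_trees: int = 1000, balanced: bool = True,
                 feature_names=None, seed: int = 0):
        self.n_trees = n_trees
        self.balanced = balanced
        self.feature_names = feature_names
        self.seed = seed

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y):
        X, names = _as_matrix(X, self.feature_names)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need both presence and background classes to fit")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 predictors")
        clf = RandomForestClassifier(
            n_estimators=self.n_trees,
            class_weight="balanced" if self.balanced else None,
            oob_score=True,
            bootstrap=True,
            n_jobs=1,
            random_state=self.seed,
        )
        clf.fit(X, y)
        oob = clf.oob_decision_function_[:, list(clf.classes_).index(1)]
        # a point sampled into every bootstrap has no OOB trees; with
        # hundreds of trees this is ~(1-1/e)^T and practically impossible
        if np.isnan(oob).any():
            raise RuntimeError("OOB score undefined for some points; grow more trees")
        self.classifier_ = clf
        self.feature_names_ = list(names)
        self.classes_ = clf.classes_
        self.oob_scores_ = oob
        self.oob_roc_auc_ = roc_auc(y, oob)
        order = np.argsort(clf.feature_importances_)[::-1]
        self.importances_ = [(names[i], float(clf.feature_importances_[i])) for i in order]
        return self

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees voting presence — the RIO score."""
        check_is_fitted(self, "classifier_")
        X, _ = _as_matrix(X, self.feature_names_)
        votes = np.zeros(X.shape[0])
        for tree in self.classifier_.estimators_:
            votes += tree.predict(X) == 1
        return votes / len(self.classifier_.estimators_)

    def predict_proba(self, X):
        check_is_fitted(self, "classifier_")
        X, _ = _as_matrix(X, self.feature_names_)
        return self.classifier_.predict_proba(X)

    def predict(self, X):
        return (self.vote_fraction(X) >= 0.5).astype(int)

    # -- persistence -----------------------------------------------------
    def save(self, model_dir: str | Path) -> Path:
        check_is_fitted(self, "classifier_")
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, model_dir / "occurrence_model.joblib")
        meta = {
            "kind": "occurrence",
            "n_trees": self.n_trees,
            "balanced": self.balanced,
            "seed": self.seed,
            "feature_names": self.feature_names_,
            "oob_roc_auc": self.oob_roc_auc_,
        }
        (model_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        return model_dir

    @staticmethod
    def load(model_dir: str | Path) -> "OccurrenceModel":
        return joblib.load(Path(model_dir) / "occurrence_model.joblib")


def _as_matrix(X, feature_names):
    """Coerce a sample-matrix DataFrame or array to (matrix, names)."""
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
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


def fit_occurrence(samples: pd.DataFrame, n_trees: int = 1000,
                   balanced: bool = True, seed: int = 0) -> OccurrenceModel:
    """Fit the occurrence model on a sample matrix with a ``presence``
    column (thin wrapper over :class:`OccurrenceModel`)."""
    model = OccurrenceModel(n_trees=n_trees, balanced=balanced, seed=seed)
    return model.fit(samples, samples["presence"].to_numpy())


def predict_rio(model: OccurrenceModel, stack: PredictorStack) -> Grid:
    """Score every valid pixel of the stack: RIO surface in [0, 1]."""
    check_is_fitted(model, "classifier_")
    missing = [n for n in model.feature_names_ if n not in stack]
    if missing:
        raise ValueError(f"stack missing predictor layers: {missing}")
    X, valid = stack.as_matrix(model.feature_names_)
    out = np.full(stack.template.shape, np.nan)
    flat = np.empty(X.shape[0])
    for start in range(0, X.shape[0], _PREDICT_CHUNK):
        block = slice(start, start + _PREDICT_CHUNK)
        flat[block] = model.vote_fraction(X[block])
    out[valid] = flat
    return stack.template.copy_with(out, nodata=~valid)


def variable_importance(model: OccurrenceModel) -> list[tuple[str, float]]:
    """All predictors with impurity-based importance, descending."""
    check_is_fitted(model, "importances_")
    return list(model.importances_)


def partial_dependence(model, samples: pd.DataFrame, variable: str,
                       n_grid: int = 100) -> list[tuple[float, float]]:
    """Substitution-average partial dependence curve.

    For each grid value v spanning the variable's observed range, the
    response is the mean model score over the training rows with the
    variable set to v (vote fraction for classifiers, mean prediction
    for regressors). The variable may be any training column; if the
    fitted model does not use it, the curve is exactly flat.
    """
    if variable not in samples.columns:
        raise ValueError(f"unknown variable {variable!r}")
    names = model.feature_names_
    X = samples[list(names)].to_numpy(dtype=float)
    var_values = samples[variable].to_numpy(dtype=float)
    grid = np.linspace(var_values.min(), var_values.max(), n_grid)
    score = model.vote_fraction if hasattr(model, "vote_fraction") else model.predict_mean
    col = names.index(variable) if variable in names else None
    curve = []
    base = float(np.mean(score(X))) if col is None else None
    for v in grid:
        if col is None:
            curve.append((float(v), base))
            continue
        Xm = X.copy()
        Xm[:, col] = v
        curve.append((float(v), float(np.mean(score(Xm)))))
    return curve
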