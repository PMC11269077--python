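"""Patient-level mortality classifier: gradient-boosted trees with
missingness filtering, recursive feature elimination, and grid search.

The workflow mirrors standard clinical prediction practice: drop
features with excessive missingness, split 75/25 stratified on the
outcome, rank features by the boosted model's gain importance and
recursively eliminate the weakest while tracking cross-validated AUC,
pick the best subset, then tune hyperparameters by exhaustive grid
search (including the positive-class weight, since in-hospital death is
a ~2% minority class), and refit on the full training split.  Missing
values are left as NaN throughout - the boosted trees route them with
their native default-direction rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.model_selection import cross_val_score
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "RfeTrace", "MortalityClassifier",
           "encode_features", "drop_sparse_features", "split_train_test",
           "rfe_select", "grid_search_fit", "predict_risk",
           "DEFAULT_XGB_PARAMS", "DEFAULT_GRID"]

#: Ordered clinical ladders encoded ordinally; other categoricals one-hot.
DEFAULT_ORDINAL_LADDERS = {
    "pulmonary_insufficiency": ["negative", "slight", "mild", "mild_moderate",
                                "moderate", "moderate_severe", "severe"],
    "left_atrial_dimension": ["below_critical", "normal", "above_critical"],
}

DEFAULT_XGB_PARAMS = dict(
    n_estimators=100, max_depth=3, learning_rate=0.2,
    tree_method="hist", n_jobs=1, eval_metric="logloss",
)

#: Default hyperparameter lattice; "auto" resolves the positive-class
#: weight to the train-set negative/positive ratio.
DEFAULT_GRID = {
    "max_depth": [3, 5],
    "learning_rate": [0.1, 0.3],
    "scale_pos_weight": [1.0, "auto"],
}


@dataclass
class FeatureMatrix:
    """Encoded train/test design matrices with outcomes and schema."""
    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    schema: dict = field(default_factory=dict)

    @property
    def feature_names(self):
        return list(self.X_train.columns)


@dataclass
class RfeTrace:
    """Elimination order, per-subset-size CV AUC, and the selected subset."""
    eliminated: list
    subset_sizes: list
    cv_auc: list
    subsets: list
    selected: list

    def as_frame(self):
        return pd.DataFrame({"subset_size": self.subset_sizes,
                             "cv_auc": self.cv_auc})


def encode_features(df, outcome_col="died_in_hospital",
                    drop_cols=("patient_id", "procedure_name"),
                    ordinal_ladders=None):
    """Encode a patient table to a numeric design matrix (NaN preserved).

    Ordered clinical categories (severity ladders, dimension-vs-critical
    categories) are encoded ordinally; unordered categoricals are one-hot
    encoded with the indicator columns set to NaN where the source value
    is missing.  Returns ``(X, y, schema)``; ``y`` is None if the outcome
    column is absent.
    """
    ladders = dict(DEFAULT_ORDINAL_LADDERS)
    if ordinal_ladders:
        ladders.update(ordinal_ladders)
    y = None
    work = df.drop(columns=[c for c in drop_cols if c in df.columns])
    if outcome_col in work.columns:
        y = work.pop(outcome_col).to_numpy(dtype=int)
    out = {}
    schema = {}
    for col in work.columns:
        s = work[col]
        if col in ladders:
            cat = pd.Categorical(s, categories=ladders[col], ordered=True)
            codes = cat.codes.astype(float)
            codes[codes < 0] = np.nan
            out[col] = codes
            schema[col] = {"encoding": "ordinal", "levels": ladders[col]}
        elif s.dtype.kind in "biufc":
            out[col] = s.to_numpy(dtype=float)
            schema[col] = {"encoding": "numeric"}
        else:
            cat = pd.Categorical(s)
            levels = list(cat.categories)
            miss = cat.codes < 0
            for lv in levels:
                ind = (np.asarray(cat) == lv).astype(float)
                ind[miss] = np.nan
                out[f"{col}={lv}"] = ind
            schema[col] = {"encoding": "onehot", "levels": levels}
    X = pd.DataFrame(out, index=df.index)
    return X, y, schema


def drop_sparse_features(X, threshold=0.30):
    """Drop features whose missing fraction strictly exceeds ``threshold``.

    A feature missing in exactly ``threshold`` of rows is retained.
    Returns ``(X_kept, report)`` where the report maps each feature to its
    missing fraction and kept/dropped status.
    """
    frac = X.isna().mean()
    dropped = frac.index[frac > threshold].tolist()
    report = {c: {"missing_fraction": float(frac[c]), "kept": c not in dropped}
              for c in X.columns}
    if len(dropped) == len(X.columns):
        raise ValueError("all features exceed the missingness threshold")
    if dropped:
        logger.info("dropped %d/%d features over %.0f%% missing: %s",
                    len(dropped), len(X.columns), 100 * threshold, dropped)
    return X.drop(columns=dropped), report


def split_train_test(X, y, ratio=0.75, stratified=True, seed=None, schema=None):
    """Stratified 75/25 train/test split into a :class:`FeatureMatrix`."""
    if len(X) < 4:
        raise ValueError("need at least 4 rows to split")
    strat = y if stratified else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=ratio, stratify=strat, random_state=seed)
    if stratified and (len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2):
        raise ValueError("a class is absent from one split")
    return FeatureMatrix(X_tr, np.asarray(y_tr), X_te, np.asarray(y_te),
                         schema or {})


def _make_xgb(params=None, seed=None, y=None):
    p = dict(DEFAULT_XGB_PARAMS)
    if params:
        p.update(params)
    if p.get("scale_pos_weight") == "auto":
        p["scale_pos_weight"] = float((np.asarray(y) == 0).sum()
                                      / max((np.asarray(y) == 1).sum(), 1))
    return XGBClassifier(random_state=0 if seed is None else seed, **p)


def _gain_importances(model, feature_names):
    booster = model.get_booster()
    score = booster.get_score(importance_type="gain")
    return np.array([score.get(f, 0.0) for f in feature_names])


def rfe_select(X, y, model_params=None, cv=5, seed=None, min_features=1):
    """Recursive feature elimination ranked by boosted-tree gain importance.

    Per round: record the stratified ``cv``-fold cross-validated AUC of
    the current subset, fit on all rows, and drop the lowest-gain feature
    (ties drop the later column, deterministically).  The selected subset
    maximises CV AUC; ties go to the smaller subset.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for elimination")
    features = list(X.columns)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    eliminated, sizes, aucs, subsets = [], [], [], []
    while len(features) >= max(min_features, 1):
        auc = cross_val_score(_make_xgb(model_params, seed, y), X[features], y,
                              cv=skf, scoring="roc_auc").mean()
        sizes.append(len(features))
        aucs.append(float(auc))
        subsets.append(list(features))
        if len(features) == max(min_features, 1):
            break
        model = _make_xgb(model_params, seed, y).fit(X[features], y)
        gains = _gain_importances(model, features)
        worst = int(np.where(gains == gains.min())[0][-1])
        eliminated.append(features.pop(worst))
    best = int(np.lexsort((sizes, -np.asarray(aucs)))[0])
    return RfeTrace(eliminated=eliminated, subset_sizes=sizes, cv_auc=aucs,
                    subsets=subsets, selected=subsets[best])


def grid_search_fit(X, y, grid=None, cv=5, seed=None, base_params=None):
    """Exhaustive grid search by stratified CV AUC; refit best on all rows.

    Returns ``(model, best_params, cv_results)``.  ``"auto"`` entries for
    ``scale_pos_weight`` resolve to the negative/positive ratio of ``y``.
    """
    grid = {k: list(v) for k, v in (grid or DEFAULT_GRID).items()}
    if "scale_pos_weight" in grid:
        ratio = float((y == 0).sum() / max((y == 1).sum(), 1))
        grid["scale_pos_weight"] = [ratio if v == "auto" else float(v)
                                    for v in grid["scale_pos_weight"]]
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    gs = GridSearchCV(_make_xgb(base_params, seed, y), grid,
                      scoring="roc_auc", cv=skf, refit=True, n_jobs=1)
    gs.fit(X, y)
    return gs.best_estimator_, dict(gs.best_params_), gs.cv_results_


def predict_risk(model, X):
    """Per-patient death probability from a fitted boosted model.

    The columns of ``X`` must cover the training schema; extra columns
    are dropped, missing ones raise.
    """
    names = list(getattr(model, "feature_names_in_", []))
    missing = [c for c in names if c not in X.columns]
    if missing:
        raise KeyError(f"feature columns missing from input: {missing}")
    return model.predict_proba(X[names])[:, 1]


class MortalityClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted in-hospital mortality classifier.

    ``fit`` takes a *numeric* design matrix (see :func:`encode_features`)
    with NaN for missing values, applies the sparsity filter, optionally
    runs recursive feature elimination, tunes hyperparameters by grid
    search, and refits on the selected features.

    Parameters
    ----------
    missing_threshold : float
        Features missing in strictly more than this fraction of rows are
        dropped before anything else.
    do_rfe : bool
        Run recursive feature elimination before the grid search.
    grid : dict or None
        Hyperparameter lattice (None: a small documented default over
        depth, learning rate and positive-class weight).
    cv : int
        Stratified folds for both RFE and grid search.
    xgb_params : dict or None
        Overrides of the base booster settings.
    random_state : int or None

    Attributes
    ----------
    features_ : selected feature names.
    rfe_trace_ : :class:`RfeTrace` (None when ``do_rfe=False``).
    best_params_ : winning grid-search settings.
    model_ : the refitted ``XGBClassifier``.
    feature_importances_ : pandas.Series
        Gain importances over the selected features, normalised to sum
        to 1.
    """

    def __init__(self, missing_threshold=0.30, do_rfe=True, grid=None,
                 cv=5, xgb_params=None, random_state=None):
        self.missing_threshold = missing_threshold
        self.do_rfe = do_rfe
        self.grid = grid
        self.cv = cv
        self.xgb_params = xgb_params
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("outcome has a single class")
        X_kept, self.sparsity_report_ = drop_sparse_features(
            X, self.missing_threshold)
        if self.do_rfe and X_kept.shape[1] >= 2:
            self.rfe_trace_ = rfe_select(X_kept, y, self.xgb_params,
                                         cv=self.cv, seed=self.random_state)
            features = self.rfe_trace_.selected
        else:
            self.rfe_trace_ = None
            features = list(X_kept.columns)
        self.features_ = features
        self.model_, self.best_params_, self.cv_results_ = grid_search_fit(
            X_kept[features], y, grid=self.grid, cv=self.cv,
            seed=self.random_state, base_params=self.xgb_params)
        self.classes_ = np.array([0, 1])
        gains = _gain_importances(self.model_, features)
        total = gains.sum()
        self.feature_importances_ = pd.Series(
            gains / total if total > 0 else gains, index=features,
            name="normalized_gain").sort_values(ascending=False)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        p1 = predict_risk(self.model_, pd.DataFrame(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
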