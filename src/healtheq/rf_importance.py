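"""Bagged-tree out-of-bag permutation importance and randomized
hyperparameter search.

Importance of a feature X is the mean over trees of the increase in that
tree's out-of-bag error after randomly permuting X's values on the
tree's OOB rows:

    OOB_store(X) = sum_i (err_oob2_i - err_oob1_i) / N

with ``err_oob1`` the baseline per-tree OOB error, ``err_oob2`` the
post-permutation error, and N the number of trees with a non-empty OOB
set.  In the default regression-on-0/1 mode the per-tree error is the
squared error (the %IncMSE convention); a classification mode using
misclassification rate is selectable.  Only OOB values are permuted, one
permutation per tree per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import randint
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_model import DegenerateDataError

__all__ = ["ForestConfig", "Forest", "ForestImportance", "fit_forest",
           "oob_importance", "random_search", "SEARCH_RANGES"]

#: Hyperparameter search ranges (inclusive) of the published search design.
SEARCH_RANGES: dict[str, tuple[int, int]] = {
    "n_estimators": (1, 500),
    "max_depth": (1, 20),
    "min_samples_split": (2, 20),
    "min_samples_leaf": (1, 10),
}


@dataclass(frozen=True)
class ForestConfig:
    """Bagged-ensemble hyperparameters (ranges per the published search).

    ``mtry`` (features considered per split) is a separate knob from
    ``min_samples_split``; ``None`` means ceil(sqrt(p)).
    """

    n_estimators: int = 200
    max_depth: int = 10
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    mtry: int | None = None
    mode: str = "regression"   # "regression" (squared error on 0/1) | "classification"
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in SEARCH_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside range [{lo}, {hi}]")
        if self.mode not in ("regression", "classification"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Forest:
    """A fitted bagged-tree ensemble with per-tree OOB bookkeeping."""

    model: object
    config: ForestConfig
    oob_indices: list[np.ndarray]   # per-tree OOB row indices
    feature_names: list[str]

    @property
    def trees(self) -> list:
        return list(self.model.estimators_)


@dataclass
class ForestImportance:
    """Per-feature OOB permutation importance with per-tree error pairs."""

    feature_names: list[str]
    err_oob1: dict[str, np.ndarray]   # baseline per-tree OOB error
    err_oob2: dict[str, np.ndarray]   # post-permutation per-tree OOB error
    n_trees: int
    oob_store: dict[str, float]
    ranking: list[str]                # features, descending score

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.ranking,
            "oob_store": [self.oob_store[f] for f in self.ranking],
            "rank": np.arange(1, len(self.ranking) + 1),
        })


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if hasattr(X, "slopes"):  # DesignMatrix
        return X.slopes(), X.slope_names()
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_forest(X, y, cfg: ForestConfig = ForestConfig()) -> Forest:
    """Fit a bagged decision-tree ensemble with bootstrap resampling.

    Accepts an integer-coded factor frame (default for importance
    ranking), a plain array, or a :class:`DesignMatrix` (one-hot).
    Per-tree out-of-bag row sets are recorded for the importance score.
    """
    cfg.validate()
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    if Xm.shape[0] < 2 or Xm.shape[1] < 1:
        raise DegenerateDataError("need at least 2 rows and 1 feature")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome has a single class")
    p = Xm.shape[1]
    mtry = cfg.mtry if cfg.mtry is not None else int(np.ceil(np.sqrt(p)))
    tree_kw = dict(max_depth=cfg.max_depth,
                   min_samples_split=cfg.min_samples_split,
                   min_samples_leaf=cfg.min_samples_leaf,
                   max_features=min(mtry, p))
    if cfg.mode == "regression":
        base = DecisionTreeRegressor(**tree_kw)
        model = BaggingRegressor(estimator=base, n_estimators=cfg.n_estimators,
                                 bootstrap=True, random_state=cfg.seed)
    else:
        base = DecisionTreeClassifier(**tree_kw)
        model = BaggingClassifier(estimator=base, n_estimators=cfg.n_estimators,
                                  bootstrap=True, random_state=cfg.seed)
    model.fit(Xm, y.astype(float) if cfg.mode == "regression" else y)
    n = Xm.shape[0]
    oob = []
    for samples in model.estimators_samples_:
        inbag = np.zeros(n, dtype=bool)
        inbag[samples] = True
        oob.append(np.flatnonzero(~inbag))
    return Forest(model=model, config=cfg, oob_indices=oob, feature_names=names)


def _tree_error(tree, X, y, mode: str) -> float:
    pred = tree.predict(X)
    if mode == "regression":
        return float(np.mean((pred - y) ** 2))
    return float(np.mean(pred != y))


def oob_importance(forest: Forest, X, y, seed: int = 0) -> ForestImportance:
    """Per-tree OOB noise-injection importance for every feature.

    For each tree and feature: baseline OOB error, then the error after
    permuting that feature's values on the OOB rows only (one permutation
    per tree per feature).  Trees with empty OOB sets are skipped and N
    decremented.
    """
    Xm, names = _as_matrix(X)
    if names != forest.feature_names and len(names) == len(forest.feature_names):
        names = forest.feature_names
    y = np.asarray(y, dtype=float if forest.config.mode == "regression" else None)
    rng = np.random.default_rng(seed)
    mode = forest.config.mode
    kept = [(t, o) for t, o in zip(forest.trees, forest.oob_indices) if len(o)]
    n_trees = len(kept)
    err1: dict[str, list[float]] = {f: [] for f in names}
    err2: dict[str, list[float]] = {f: [] for f in names}
    for tree, oob in kept:
        Xo, yo = Xm[oob], y[oob]
        base_err = _tree_error(tree, Xo, yo, mode)
        for j, f in enumerate(names):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            err1[f].append(base_err)
            err2[f].append(_tree_error(tree, Xp, yo, mode))
    store = {f: float(np.mean(np.array(err2[f]) - np.array(err1[f])))
             for f in names}
    ranking = sorted(names, key=lambda f: store[f], reverse=True)
    return ForestImportance(
        feature_names=names,
        err_oob1={f: np.array(v) for f, v in err1.items()},
        err_oob2={f: np.array(v) for f, v in err2.items()},
        n_trees=n_trees, oob_store=store, ranking=ranking)


@dataclass
class SearchResult:
    best_config: ForestConfig
    best_score: float
    trials: pd.DataFrame
    cv: object = field(default=None, repr=False)


def random_search(X, y, ranges: dict[str, tuple[int, int]] | None = None,
                  n_iter: int = 20, k_folds: int = 5, seed: int = 0) -> SearchResult:
    """Randomized hyperparameter search with stratified k-fold CV accuracy.

    Draws ``n_iter`` parameter combinations uniformly over the inclusive
    ranges and returns the accuracy-maximizing configuration plus the
    full trial log (params, per-fold accuracies, mean).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ranges = ranges or SEARCH_RANGES
    Xm, _ = _as_matrix(X)
    y = np.asarray(y)
    dists = {name: randint(lo, hi + 1) for name, (lo, hi) in ranges.items()}
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=seed),
        param_distributions=dists, n_iter=n_iter, scoring="accuracy",
        cv=cv, random_state=seed, refit=False)
    search.fit(Xm, y)
    res = pd.DataFrame(search.cv_results_)
    fold_cols = [c for c in res.columns if c.startswith("split")]
    trials = pd.concat([pd.DataFrame(list(res["params"])),
                        res[fold_cols + ["mean_test_score"]]], axis=1)
    best = search.best_params_
    cfg = ForestConfig(n_estimators=best["n_estimators"],
                       max_depth=best["max_depth"],
                       min_samples_split=best["min_samples_split"],
                       min_samples_leaf=best["min_samples_leaf"],
                       mode="classification", seed=seed)
    return SearchResult(best_config=cfg, best_score=float(search.best_score_),
                        trials=trials, cv=cv)
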