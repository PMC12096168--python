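"""L1-penalized logistic variable selection over a lambda path with k-fold
cross-validation.

The path solves, per lambda on a descending log-spaced grid from
lambda_max (the smallest penalty at which every penalized coefficient is
zero),

    min_{b0, b}  (1/n) * sum_i loss(y_i, b0 + x_i b) + lambda * ||b||_1

with the intercept unpenalized and predictors standardized before
penalization (coefficients are reported back on the original scale).
``lambda_min`` minimizes the cross-validated loss; ``lambda_1se`` is the
largest lambda within one standard error of that minimum (the
parsimonious choice).  A factor is *selected* at a given lambda iff any
of its dummy columns has a nonzero coefficient.

A linear-Gaussian family is included for closed-form verification
(single standardized predictor reduces to the soft-threshold formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["LassoPath", "CvResult", "fit_lasso_path", "cv_select",
           "selected_factors"]

_ZERO_TOL = 1e-8


@dataclass
class LassoPath:
    """Coefficients along a descending lambda grid (original scale)."""

    lambdas: np.ndarray         # descending
    coef: np.ndarray            # (n_lambdas, p)
    intercept: np.ndarray       # (n_lambdas,)
    column_names: list[str]
    family: str

    def coef_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        if not np.isclose(self.lambdas[idx], lam, rtol=1e-6, atol=1e-12):
            raise ValueError(f"lambda {lam} not on the path grid")
        return self.coef[idx]

    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coef) > _ZERO_TOL).sum(axis=1)


def _design(X) -> tuple[np.ndarray, list[str]]:
    if hasattr(X, "slopes"):  # DesignMatrix: drop the intercept column
        return X.slopes(), X.slope_names()
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def lambda_max(X, y, family: str = "binomial") -> float:
    """Smallest penalty with an all-zero solution: max_j |<x_j, y - ybar>|/n
    on standardized predictors."""
    Xs, _, _ = _standardize(_design(X)[0])
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))


def fit_lasso_path(X, y, n_lambdas: int = 60, lambda_min_ratio: float = 1e-3,
                   standardize: bool = True, family: str = "binomial",
                   max_iter: int = 100, lambdas=None) -> LassoPath:
    """Solve the penalized path on a log-spaced descending lambda grid.

    ``max_iter`` caps the solver's iterations per lambda (warm-started
    down the grid).  An explicit ``lambdas`` grid overrides the automatic
    one (used by cross-validation to share a grid across folds).
    """
    Xraw, names = _design(X)
    y = np.asarray(y, dtype=float)
    if family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial family requires a 0/1 outcome")
    if Xraw.shape[1] < 1:
        raise ValueError("need at least one penalized column")
    if standardize:
        Xs, mean, scale = _standardize(Xraw)
    else:
        Xs, mean, scale = Xraw, np.zeros(Xraw.shape[1]), np.ones(Xraw.shape[1])
    n, p = Xs.shape
    if lambdas is None:
        lmax = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)
    coef_std = np.zeros((len(lambdas), p))
    icept_std = np.zeros(len(lambdas))
    if family == "binomial":
        clf = LogisticRegression(l1_ratio=1.0, solver="saga", warm_start=True,
                                 fit_intercept=True, max_iter=max_iter,
                                 tol=1e-7, random_state=0)
        for i, lam in enumerate(lambdas):
            clf.set_params(C=1.0 / (n * lam))
            clf.fit(Xs, y)
            coef_std[i] = clf.coef_[0]
            icept_std[i] = clf.intercept_[0]
    elif family == "gaussian":
        for i, lam in enumerate(lambdas):
            reg = Lasso(alpha=lam, fit_intercept=True, max_iter=max(max_iter, 1000))
            reg.fit(Xs, y)
            coef_std[i] = reg.coef_
            icept_std[i] = reg.intercept_
    else:
        raise ValueError(f"unknown family {family!r}")
    coef = coef_std / scale[None, :]
    intercept = icept_std - coef_std @ (mean / scale)
    return LassoPath(lambdas=lambdas, coef=coef, intercept=intercept,
                     column_names=names, family=family)


@dataclass
class CvResult:
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    path: LassoPath           # full-data path on the shared grid


def _fold_loss(path: LassoPath, i: int, X: np.ndarray, y: np.ndarray,
               loss: str) -> float:
    eta = path.intercept[i] + X @ path.coef[i]
    if path.family == "binomial":
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        if loss == "deviance":
            return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return float(np.mean((y - p) ** 2))
    return float(np.mean((y - eta) ** 2))


def cv_select(X, y, k: int = 10, seed: int = 0, loss: str = "deviance",
              **path_kwargs) -> CvResult:
    """k-fold cross-validation over a shared lambda grid.

    Folds are stratified on the outcome (a single-class fold would leave
    the binomial loss undefined).  ``loss`` is binomial deviance by
    default; squared error on the predicted probability is selectable.
    Returns the CV curve with ``lambda_min`` (curve minimizer) and
    ``lambda_1se`` (largest lambda within one SE of the minimum).
    """
    Xraw, _ = _design(X)
    y = np.asarray(y, dtype=float)
    if k > len(y):
        raise ValueError("more folds than observations")
    full = fit_lasso_path(X, y, **path_kwargs)
    grid = full.lambdas
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < k:
        raise ValueError("a class is too small for stratified folding")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    losses = np.zeros((k, len(grid)))
    for f, (tr, te) in enumerate(folds.split(Xraw, y)):
        sub = fit_lasso_path(Xraw[tr], y[tr], lambdas=grid,
                             **{kk: v for kk, v in path_kwargs.items()
                                if kk not in ("n_lambdas", "lambda_min_ratio")})
        for i in range(len(grid)):
            losses[f, i] = _fold_loss(sub, i, Xraw[te], y[te], loss)
    cv_mean = losses.mean(axis=0)
    cv_se = losses.std(axis=0, ddof=1) / np.sqrt(k)
    imin = int(np.argmin(cv_mean))
    lambda_min = float(grid[imin])
    within = cv_mean <= cv_mean[imin] + cv_se[imin]
    lambda_1se = float(grid[np.flatnonzero(within).min()])  # grid is descending
    return CvResult(lambdas=grid, cv_mean=cv_mean, cv_se=cv_se,
                    lambda_min=lambda_min, lambda_1se=lambda_1se, path=full)


def selected_factors(path: LassoPath, lam: float,
                     grouping: dict[str, str] | None = None) -> list[str]:
    """Factors with any nonzero dummy coefficient at the given lambda.

    ``grouping`` maps column name -> factor; without it each column is
    its own factor.  Order follows first appearance among the columns.
    """
    coefs = path.coef_at(lam)
    grouping = grouping or {c: c for c in path.column_names}
    out: list[str] = []
    for name, b in zip(path.column_names, coefs):
        factor = grouping.get(name, name)
        if abs(b) > _ZERO_TOL and factor not in out:
            out.append(factor)
    return out
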