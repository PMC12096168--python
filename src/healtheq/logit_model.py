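"""Binary logistic regression on the selected factors: maximum-likelihood
coefficients, Wald standard errors, odds ratios with 95% intervals, and
average marginal effects on the probability scale.

The model is  logit P(y=1 | x) = b0 + x'b  fitted by Newton iterations
(iteratively reweighted least squares) to a tight gradient tolerance via
statsmodels.  All regressors here are 0/1 dummies, so the marginal
effect of column j is the discrete change: the mean over respondents of
p_hat(x with column j = 1) - p_hat(x with column j = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import codebook as cb
from .data_model import DesignMatrix

__all__ = ["LogitFit", "SeparationError", "CollinearityError", "fit_logit",
           "odds_ratio_table", "average_marginal_effects"]

#: Wald 95% multiplier used by the published intervals.
Z95 = 1.96


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect or quasi separation)."""


class CollinearityError(ValueError):
    """The design matrix is rank-deficient."""


@dataclass
class LogitFit:
    """Fitted binary logit with Wald inference and marginal effects."""

    column_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    or_: np.ndarray                  # exp(beta)
    ci95: np.ndarray                 # (p, 2): exp(beta -/+ 1.96 se)
    ame: np.ndarray                  # average marginal effects (const -> nan slot 0)
    mu_hat: float
    loglik: float
    n: int
    converged: bool


def _check_collinearity(X: DesignMatrix) -> None:
    vals = X.values
    rank = np.linalg.matrix_rank(vals)
    if rank < vals.shape[1]:
        # name a minimal offending column via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(vals, pivoting=True, mode="economic")
        bad = [X.column_names[j] for j in piv[rank:]]
        raise CollinearityError(f"collinear design columns: {bad}")


def fit_logit(X: DesignMatrix, y) -> LogitFit:
    """Maximum-likelihood logistic fit with Wald standard errors.

    Raises :class:`CollinearityError` on a rank-deficient design and
    :class:`SeparationError` when the iterations diverge (a coefficient
    running off to +/- infinity under separation).
    """
    y = np.asarray(y, dtype=float)
    _check_collinearity(X)
    model = sm.Logit(y, X.values)
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        raise SeparationError(str(e)) from e
    beta = np.asarray(res.params)
    if not res.mle_retvals.get("converged", False) or np.max(np.abs(beta)) > 30:
        raise SeparationError(
            "logit did not converge (possible separation); "
            f"max |beta| = {np.max(np.abs(beta)):.2f}")
    se = np.asarray(res.bse)
    lo = np.exp(beta - Z95 * se)
    hi = np.exp(beta + Z95 * se)
    fit = LogitFit(
        column_names=list(X.column_names),
        beta=beta, se=se, pvalues=np.asarray(res.pvalues),
        or_=np.exp(beta), ci95=np.column_stack([lo, hi]),
        ame=np.full_like(beta, np.nan),
        mu_hat=float(np.mean(res.predict())),
        loglik=float(res.llf), n=len(y),
        converged=bool(res.mle_retvals.get("converged", False)),
    )
    fit.ame = average_marginal_effects(fit, X)
    return fit


def predicted_probability(fit: LogitFit, values: np.ndarray) -> np.ndarray:
    return expit(values @ fit.beta)


def average_marginal_effects(fit: LogitFit, X: DesignMatrix,
                             binary_tol: float = 0.0) -> np.ndarray:
    """Average marginal effect of each design column on P(y=1).

    Dummy (0/1) columns use the discrete change  mean_i[p_i(x_j=1) -
    p_i(x_j=0)]  holding all other columns at their observed values;
    a non-binary column falls back to the derivative approximation
    mean_i[p_i (1 - p_i)] * beta_j.  The intercept slot is NaN.
    """
    vals = X.values
    out = np.full(vals.shape[1], np.nan)
    p_obs = predicted_probability(fit, vals)
    for j, name in enumerate(X.column_names):
        if name == "const":
            continue
        col = vals[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            hi = vals.copy(); hi[:, j] = 1.0
            lo = vals.copy(); lo[:, j] = 0.0
            out[j] = float(np.mean(predicted_probability(fit, hi)
                                   - predicted_probability(fit, lo)))
        else:
            out[j] = float(np.mean(p_obs * (1 - p_obs)) * fit.beta[j])
    return out


def odds_ratio_table(fit: LogitFit, X: DesignMatrix | None = None) -> pd.DataFrame:
    """Regression table in the published layout: one row per factor level,
    reference rows annotated, with beta, p, OR and the Wald 95% interval."""
    rows = []
    ref_emitted: set[str] = set()
    factor_of = X.factor_of_column if X is not None else {}
    refs = X.reference_groups if X is not None else {}
    for k, name in enumerate(fit.column_names):
        if name == "const":
            rows.append({"factor": "(intercept)", "level": "", "reference": False,
                         "beta": fit.beta[k], "p": fit.pvalues[k],
                         "or": fit.or_[k], "ci_low": fit.ci95[k, 0],
                         "ci_high": fit.ci95[k, 1], "ame": np.nan})
            continue
        factor = factor_of.get(name, name.rsplit("_", 1)[0])
        if factor not in ref_emitted and factor in refs:
            ref = refs[factor]
            rows.append({"factor": factor,
                         "level": cb.LEVEL_LABELS.get(factor, {}).get(ref, str(ref))
                         + " (reference group)",
                         "reference": True, "beta": np.nan, "p": np.nan,
                         "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "ame": np.nan})
            ref_emitted.add(factor)
        lvl = int(name.rsplit("_", 1)[1]) if name.rsplit("_", 1)[1].isdigit() else name
        rows.append({"factor": factor,
                     "level": cb.LEVEL_LABELS.get(factor, {}).get(lvl, str(lvl)),
                     "reference": False,
                     "beta": fit.beta[k], "p": fit.pvalues[k],
                     "or": fit.or_[k], "ci_low": fit.ci95[k, 0],
                     "ci_high": fit.ci95[k, 1], "ame": fit.ame[k]})
    return pd.DataFrame(rows)
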