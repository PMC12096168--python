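"""Income-rank equity analysis: fractional ranks, the concentration index
and curve, and the Wagstaff decomposition of the index into factor
contributions.

The concentration index of an outcome :math:`y` over income ranks
:math:`R` is

.. math:: CI = \\frac{2\\,\\mathrm{cov}(y, R)}{\\mu},

with :math:`\\mu` the mean outcome and :math:`R_i` the weighted fractional
(midpoint) rank in the income distribution.  ``CI > 0`` is pro-rich
inequality (utilization concentrated among richer respondents),
``CI < 0`` pro-poor.  The decomposition writes the index of the outcome
as a sum over model determinants,

.. math:: C = \\sum_j \\eta_j C_j + \\frac{GC_\\varepsilon}{\\mu},
          \\qquad \\eta_j = \\frac{ME_j\\,\\bar X_j}{\\mu},

where :math:`\\eta_j` is determinant *j*'s elasticity (average marginal
effect times its mean over the outcome mean), :math:`C_j` its own
concentration index over the same income ranks, and the residual term
closes the identity exactly.

Covariances are population covariances (divide by total weight, not
weight minus one), the convention of the concentration-index literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankVector",
    "ConcentrationResult",
    "DecompositionTable",
    "fractional_rank",
    "concentration_index",
    "concentration_curve_points",
    "wagstaff_decompose",
    "erreygers_correct",
]


@dataclass(frozen=True)
class RankVector:
    """Weighted fractional income ranks in (0, 1), weighted mean 0.5.

    Rank of respondent *i* is (cumulative weight of strictly poorer
    respondents + half the weight of *i*'s tied block)/total weight;
    every member of a tied income block shares the block midpoint.
    """

    r: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> int:
        return self.r.shape[0]


def fractional_rank(income, weights=None) -> RankVector:
    """Weighted fractional (midpoint) ranks of ``income``.

    Ties share the midpoint of their tied block, so all-equal incomes all
    rank 0.5 and the weighted mean rank is exactly 0.5 by construction.
    """
    income = np.asarray(income, dtype=float)
    if income.size == 0:
        raise ValueError("empty income vector")
    if not np.all(np.isfinite(income)):
        raise ValueError("income must be finite")
    w = (np.ones_like(income) if weights is None
         else np.asarray(weights, dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    total = w.sum()
    order = np.argsort(income, kind="stable")
    inc_s, w_s = income[order], w[order]
    # block boundaries of tied incomes in sorted order
    new_block = np.empty(len(inc_s), dtype=bool)
    new_block[0] = True
    new_block[1:] = inc_s[1:] != inc_s[:-1]
    block_id = np.cumsum(new_block) - 1
    block_w = np.bincount(block_id, weights=w_s)
    cum_before = np.concatenate(([0.0], np.cumsum(block_w)[:-1]))
    block_mid = (cum_before + block_w / 2.0) / total
    r_sorted = block_mid[block_id]
    r = np.empty_like(r_sorted)
    r[order] = r_sorted
    return RankVector(r=r, weights=w)


def _wcov(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    """Weighted population covariance."""
    tw = w.sum()
    am = float(np.dot(w, a) / tw)
    bm = float(np.dot(w, b) / tw)
    return float(np.dot(w, (a - am) * (b - bm)) / tw)


@dataclass(frozen=True)
class ConcentrationResult:
    ci: float
    mu: float
    curve: np.ndarray  # (k+1, 2): cumulative population share, outcome share
    direction: str     # "pro-rich" | "pro-poor" | "neutral"


def concentration_index(y, ranks: RankVector) -> ConcentrationResult:
    """Concentration index ``2 cov(y, r)/mu`` with its concentration curve."""
    y = np.asarray(y, dtype=float)
    if y.shape != ranks.r.shape:
        raise ValueError("y and ranks must align")
    w = ranks.weights
    mu = float(np.dot(w, y) / w.sum())
    if mu == 0:
        raise ValueError("undefined concentration index: outcome mean is 0")
    ci = 2.0 * _wcov(y, ranks.r, w) / mu
    curve = concentration_curve_points(y, ranks)
    direction = "pro-rich" if ci > 0 else ("pro-poor" if ci < 0 else "neutral")
    return ConcentrationResult(ci=ci, mu=mu, curve=curve, direction=direction)


def concentration_curve_points(y, ranks: RankVector) -> np.ndarray:
    """Concentration curve: cumulative outcome share vs population share.

    Points step through respondents poorest-to-richest (stable in input
    order within ties), starting at (0, 0) and ending at (1, 1); the
    curve lies below the diagonal when the index is positive.
    """
    y = np.asarray(y, dtype=float)
    w = ranks.weights
    order = np.argsort(ranks.r, kind="stable")
    cw = np.cumsum(w[order]) / w.sum()
    tot = float(np.dot(w, y))
    if tot == 0:
        raise ValueError("outcome total is 0; curve undefined")
    cy = np.cumsum((w * y)[order]) / tot
    return np.vstack([[0.0, 0.0], np.column_stack([cw, cy])])


def curve_signed_area(curve: np.ndarray) -> float:
    """Signed area between the diagonal and the curve (positive when the
    curve lies below the diagonal); twice this area approximates the index."""
    x, ycum = curve[:, 0], curve[:, 1]
    diff = x - ycum
    return float(np.trapezoid(diff, x))


@dataclass
class DecompositionTable:
    """Per-determinant decomposition of the outcome concentration index."""

    table: pd.DataFrame          # column, elasticity, factor_ci, contribution, rate, flagged
    total_ci: float
    mu: float
    residual_term: float         # GC_eps / mu, closes the identity

    def explained(self) -> float:
        return float(self.table["contribution"].sum())


def wagstaff_decompose(fit, X, ranks: RankVector, y) -> DecompositionTable:
    """Decompose the outcome's concentration index into determinant
    contributions using the fitted model's average marginal effects.

    For each non-intercept design column *j*: elasticity
    ``AME_j * mean(X_j) / mu``, factor index ``C_j = 2 cov(X_j, r) /
    mean(X_j)``, contribution ``elasticity * C_j``, and contribution rate
    ``contribution / C * 100``.  The residual term is ``C`` minus the sum
    of contributions, so the identity holds to machine precision by
    construction.  Zero-mean columns are flagged and contribute 0.

    Parameters
    ----------
    fit : LogitFit
        Fitted logistic model carrying per-column AMEs.
    X : DesignMatrix
        Design matrix the model was fitted on (same rows as ``y``).
    ranks : RankVector
        Income ranks shared by the outcome index and every factor index
        (required for the identity).
    y : array-like
        Binary outcome.
    """
    if list(fit.column_names) != list(X.column_names):
        raise ValueError("fit and design matrix columns do not match")
    y = np.asarray(y, dtype=float)
    w = ranks.weights
    overall = concentration_index(y, ranks)
    c, mu = overall.ci, overall.mu
    rows = []
    for k, name in enumerate(X.column_names):
        if name == "const":
            continue
        xj = X.values[:, k]
        xbar = float(np.dot(w, xj) / w.sum())
        ame = float(fit.ame[k])
        flagged = xbar == 0.0
        if flagged:
            elas, cj, contrib = 0.0, 0.0, 0.0
        else:
            elas = ame * xbar / mu
            cj = 2.0 * _wcov(xj, ranks.r, w) / xbar
            contrib = elas * cj
        rate = contrib / c * 100.0 if c != 0 else np.nan
        rows.append({"column": name, "mean": xbar, "ame": ame,
                     "elasticity": elas, "factor_ci": cj,
                     "contribution": contrib, "rate": rate, "flagged": flagged})
    table = pd.DataFrame(rows)
    residual = c - float(table["contribution"].sum())
    return DecompositionTable(table=table, total_ci=c, mu=mu,
                              residual_term=residual)


def erreygers_correct(result: ConcentrationResult) -> float:
    """Erreygers-corrected index for a binary outcome, ``4 mu CI / (1 - 0)``.

    Provided as an option; the headline analysis reports the plain index.
    """
    return 4.0 * result.mu * result.ci
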