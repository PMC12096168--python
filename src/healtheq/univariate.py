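"""Univariate screening: factor x outcome cross-tabulations and Pearson
chi-square independence tests (no continuity correction, matching the
published 2x2 statistics)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import codebook as cb
from .data_model import DegenerateDataError, SurveyTable

__all__ = ["ContingencyTable", "ChiSquareResult", "crosstab", "chi2_test",
           "chi2_screen", "summary_frame"]


@dataclass(frozen=True)
class ContingencyTable:
    """Factor-level x binary-outcome counts with margins.

    ``counts[l, o]`` is the number of respondents at level ``levels[l]``
    with outcome ``o`` (columns ordered outcome = 0 then 1).  Column
    percentages are within-outcome, as descriptive tables print them.
    """

    factor: str
    levels: tuple[int, ...]
    counts: np.ndarray

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def column_percent(self) -> np.ndarray:
        return 100.0 * self.counts / self.col_margins[None, :]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def crosstab(table: SurveyTable, factor: str) -> ContingencyTable:
    """Cross-tabulate a factor against the binary outcome."""
    if table.n == 0:
        raise DegenerateDataError("empty table")
    if factor not in table.df.columns:
        raise KeyError(f"unknown factor {factor!r}")
    f = table.df[factor].to_numpy()
    y = table.df[cb.OUTCOME].to_numpy()
    levels = tuple(int(v) for v in np.unique(f))
    counts = np.zeros((len(levels), 2), dtype=np.int64)
    for i, lvl in enumerate(levels):
        for o in (0, 1):
            counts[i, o] = int(np.sum((f == lvl) & (y == o)))
    return ContingencyTable(factor=factor, levels=levels, counts=counts)


def chi2_test(ct) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Accepts a :class:`ContingencyTable` or a raw counts array.  Expected
    counts come from the margin products; no Yates continuity correction
    is applied.  A zero margin raises, naming the empty level/column.
    """
    counts = ct.counts if isinstance(ct, ContingencyTable) else np.asarray(ct)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if np.any(rows == 0):
        lvl = int(np.flatnonzero(rows == 0)[0])
        label = (ct.levels[lvl] if isinstance(ct, ContingencyTable) else lvl)
        raise DegenerateDataError(f"empty factor level {label!r}")
    if np.any(cols == 0):
        raise DegenerateDataError(
            f"empty outcome column {int(np.flatnonzero(cols == 0)[0])}")
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def chi2_screen(table: SurveyTable, factors: list[str] | None = None,
                alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Test every factor against the outcome; keep those with p < alpha.

    Returns the retained factor list (input order) and a summary frame.
    """
    factors = factors if factors is not None else cb.FACTORS
    rows, kept = [], []
    for f in factors:
        res = chi2_test(crosstab(table, f))
        keep = res.p_value < alpha
        if keep:
            kept.append(f)
        rows.append({"factor": f, "statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value, "kept": keep})
    return kept, pd.DataFrame(rows)


def summary_frame(table: SurveyTable, factors: list[str] | None = None) -> pd.DataFrame:
    """Long-format univariate summary (one row per factor level) mirroring
    the layout of published baseline-difference tables."""
    factors = factors if factors is not None else cb.FACTORS
    rows = []
    for f in factors:
        ct = crosstab(table, f)
        res = chi2_test(ct)
        pct = ct.column_percent
        for i, lvl in enumerate(ct.levels):
            rows.append({
                "factor": f,
                "level": lvl,
                "label": cb.LEVEL_LABELS.get(f, {}).get(lvl, str(lvl)),
                "n_no": int(ct.counts[i, 0]),
                "pct_no": pct[i, 0],
                "n_yes": int(ct.counts[i, 1]),
                "pct_yes": pct[i, 1],
                "chi2": res.statistic if i == 0 else np.nan,
                "df": res.df if i == 0 else np.nan,
                "p": res.p_value if i == 0 else np.nan,
            })
    return pd.DataFrame(rows)
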