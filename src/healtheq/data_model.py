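"""Respondent-level data model: loading, validation, cleaning, within-province
income quintiles, and dummy (one-hot) design-matrix encoding.

The in-memory container is a thin wrapper over a pandas DataFrame whose
columns follow :mod:`healtheq.codebook`.  All downstream stages (screening,
forest importance, penalized selection, logistic fit, equity decomposition)
consume either the table or the design matrix produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codebook as cb

__all__ = [
    "SurveyTable",
    "DesignMatrix",
    "CleaningRules",
    "SchemaError",
    "ValidationError",
    "DegenerateDataError",
    "load_survey",
    "write_survey",
    "clean",
    "assign_income_quintiles",
    "dummy_encode",
]

#: Strings treated as missing in survey export files.
NA_VALUES = ["", "NA"]


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class ValidationError(ValueError):
    """A value falls outside its factor's code set."""


class DegenerateDataError(ValueError):
    """An operation received data it cannot meaningfully process."""


@dataclass
class SurveyTable:
    """Respondent-level categorical microdata.

    One row per respondent; categorical columns use the integer codes of
    the codebook, plus raw household income and a province label.
    ``income_quintile`` may be absent until derived.
    """

    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "SurveyTable":
        return SurveyTable(self.df.copy())

    def validate(self, allow_missing: bool = False) -> None:
        """Check every categorical value against its code set.

        Raises :class:`ValidationError` naming the first offending row and
        field.  With ``allow_missing``, NaNs pass (pre-cleaning state).
        """
        for col, codes in cb.CODE_SETS.items():
            if col not in self.df.columns:
                continue
            vals = self.df[col]
            mask = ~vals.isin(codes)
            if allow_missing:
                mask &= vals.notna()
            if mask.any():
                row = int(np.flatnonzero(mask.to_numpy())[0])
                raise ValidationError(
                    f"row {row}: field {col!r} has value {vals.iloc[row]!r} "
                    f"outside code set {codes}"
                )
        if cb.INCOME_RAW in self.df.columns:
            inc = self.df[cb.INCOME_RAW]
            bad = inc.notna() & (inc < 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(f"row {row}: negative {cb.INCOME_RAW}")


@dataclass
class DesignMatrix:
    """0/1 indicator matrix with an intercept column.

    One column per non-reference level of each encoded factor, in factor
    order then ascending level order; reference levels are omitted.
    """

    column_names: list[str]          # includes leading "const"
    values: np.ndarray               # shape (n, len(column_names))
    reference_groups: dict[str, int]
    factor_of_column: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def slopes(self) -> np.ndarray:
        """The matrix without its intercept column."""
        return self.values[:, 1:]

    def slope_names(self) -> list[str]:
        return self.column_names[1:]


def load_survey(path, required: list[str] | None = None) -> SurveyTable:
    """Read a delimited-text survey export (CSV/TSV, delimiter sniffed).

    Values are validated against the codebook; missing values ("" or "NA")
    are tolerated at load time and handled by :func:`clean`.
    """
    df = pd.read_csv(path, sep=None, engine="python", na_values=NA_VALUES,
                     keep_default_na=False)
    required = required or (cb.FACTORS + [cb.OUTCOME, cb.INCOME_RAW, cb.PROVINCE])
    missing = [c for c in required if c not in df.columns]
    # income_quintile is derivable, not required on disk
    missing = [c for c in missing if c != "income_quintile"]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    table = SurveyTable(df)
    table.validate(allow_missing=True)
    return table


def write_survey(table: SurveyTable, path) -> None:
    """Write the table back to CSV (round-trips through :func:`load_survey`)."""
    table.df.to_csv(path, index=False)


@dataclass(frozen=True)
class CleaningRules:
    """Row-exclusion rules applied after loading.

    The source survey reports only pre/post cleaning sample sizes, not the
    rules; these defaults (drop incomplete rows, drop non-positive and
    extreme-upper-tail incomes) are this package's documented choice.
    """

    drop_missing: bool = True
    income_positive: bool = True
    income_upper_quantile: float | None = 0.999


def clean(table: SurveyTable,
          rules: CleaningRules = CleaningRules()) -> tuple[SurveyTable, dict[str, int]]:
    """Apply the cleaning rules; return the retained table and a report.

    The report maps rule name -> rows dropped by that rule (applied in
    order: missing fields, non-positive income, income upper tail).
    """
    df = table.df
    report: dict[str, int] = {}
    required = [c for c in cb.FACTORS + [cb.OUTCOME, cb.INCOME_RAW, cb.PROVINCE]
                if c in df.columns]
    if rules.drop_missing:
        keep = df[required].notna().all(axis=1)
        report["missing_required"] = int((~keep).sum())
        df = df[keep]
    if rules.income_positive and cb.INCOME_RAW in df.columns:
        keep = df[cb.INCOME_RAW] > 0
        report["income_nonpositive"] = int((~keep).sum())
        df = df[keep]
    if rules.income_upper_quantile is not None and cb.INCOME_RAW in df.columns and len(df):
        cut = df[cb.INCOME_RAW].quantile(rules.income_upper_quantile)
        keep = df[cb.INCOME_RAW] <= cut
        report["income_upper_tail"] = int((~keep).sum())
        df = df[keep]
    if len(df) == 0:
        raise DegenerateDataError("cleaning removed every row")
    return SurveyTable(df.reset_index(drop=True)), report


#: Band edges of the five percentile bands.  Band k covers percentiles in
#: [0.2(k-1), 0.2k): a rank exactly on an edge belongs to the upper band,
#: per the "<20th percentile" convention (the lowest band is strictly
#: below the 20th percentile; the top band is ">= 80th").
_BAND_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


def assign_income_quintiles(table: SurveyTable) -> SurveyTable:
    """Assign within-province income quintiles from raw household income.

    Each respondent's percentile is their income's max-rank within the
    province divided by the province's size, so tied incomes share a band
    (a province with one distinct income lands entirely in one band).
    Percentiles exactly on a 20/40/60/80 edge belong to the upper band
    (the lowest band is strictly below the 20th percentile).
    Rank-based, hence invariant to monotone income transforms.
    """
    df = table.df.copy()
    if cb.INCOME_RAW not in df.columns or cb.PROVINCE not in df.columns:
        raise SchemaError("income_raw and province are required for quintiles")
    pct = (df.groupby(cb.PROVINCE)[cb.INCOME_RAW]
             .rank(method="max") / df.groupby(cb.PROVINCE)[cb.INCOME_RAW].transform("size"))
    p = pct.to_numpy(dtype=float)
    quintile = 1 + np.sum(p[:, None] >= _BAND_EDGES[None, :] - 1e-12, axis=1)
    df["income_quintile"] = quintile.astype(int)
    return SurveyTable(df)


def dummy_encode(table: SurveyTable,
                 factors: list[str] | None = None,
                 references: dict[str, int] | None = None) -> DesignMatrix:
    """One-hot encode the given factors with an explicit reference level.

    Columns appear in ``factors`` order, levels ascending, reference level
    omitted; a leading intercept column of ones is included.  A factor
    whose observed data contain only its reference level contributes no
    columns (degenerate, but tolerated).
    """
    import warnings

    factors = factors if factors is not None else cb.MODEL_FACTORS
    references = references or {f: cb.REFERENCE_LEVELS[f] for f in factors}
    n = table.n
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["const"]
    factor_of: dict[str, str] = {}
    for f in factors:
        codes = cb.CODE_SETS[f]
        ref = references[f]
        if ref not in codes:
            raise ValueError(f"reference level {ref} not in code set of {f!r}")
        vals = table.df[f].to_numpy()
        observed = set(np.unique(vals).tolist())
        if len(observed) < 2:
            warnings.warn(f"factor {f!r} has a single observed level; "
                          "no indicator columns emitted", stacklevel=2)
            continue
        for lvl in codes:
            if lvl == ref or lvl not in observed:
                continue
            name = cb.dummy_name(f, lvl)
            cols.append((vals == lvl).astype(float))
            names.append(name)
            factor_of[name] = f
    X = np.column_stack(cols)
    return DesignMatrix(names, X, {f: references[f] for f in factors}, factor_of)
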