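"""L1-penalized logistic selection of key factors.

Fits the penalized path over the screened factors' dummies on a
descending lambda grid, picks lambda by 10-fold cross-validated
deviance, and extracts the selected factor set (any nonzero dummy at
lambda_min; the parsimonious lambda_1se set is reported alongside).
"""

import json
from pathlib import Path

import pandas as pd

from healtheq import codebook as cb
from healtheq.data_model import dummy_encode, load_survey
from healtheq.lasso_select import cv_select, selected_factors
from healtheq.univariate import chi2_screen

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2018


def main() -> None:
    table = load_survey(RESULTS / "synthetic_survey.csv")
    kept, _ = chi2_screen(table)
    X = dummy_encode(table, kept, {f: cb.REFERENCE_LEVELS[f] for f in kept})
    y = table.df[cb.OUTCOME].to_numpy()

    cv = cv_select(X, y, k=10, seed=SEED, n_lambdas=50)
    pd.DataFrame({"lambda": cv.lambdas, "cv_deviance": cv.cv_mean,
                  "cv_se": cv.cv_se}).to_csv(RESULTS / "lasso_cv_curve.csv",
                                             index=False)
    pd.DataFrame(cv.path.coef, columns=cv.path.column_names).assign(
        **{"lambda": cv.path.lambdas}).to_csv(RESULTS / "lasso_path.csv",
                                              index=False)
    sel_min = selected_factors(cv.path, cv.lambda_min, X.factor_of_column)
    sel_1se = selected_factors(cv.path, cv.lambda_1se, X.factor_of_column)
    with open(RESULTS / "selected_factors.json", "w") as fh:
        json.dump({"lambda_min": cv.lambda_min, "lambda_1se": cv.lambda_1se,
                   "selected_min": sel_min, "selected_1se": sel_1se}, fh,
                  indent=2)
    print(f"lambda_min = {cv.lambda_min:.6f}, lambda_1se = {cv.lambda_1se:.6f}")
    print(f"selected at lambda_min  ({len(sel_min)}): {', '.join(sel_min)}")
    print(f"selected at lambda_1se ({len(sel_1se)}): {', '.join(sel_1se)}")


if __name__ == "__main__":
    main()
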