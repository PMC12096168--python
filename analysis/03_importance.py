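"""Out-of-bag permutation importance of the screened factors.

Fits a bagged decision-tree ensemble (regression on the 0/1 outcome) and
scores each factor by the mean per-tree increase in OOB error after
permuting that factor's OOB values.  A small randomized hyperparameter
search (5-fold CV accuracy) is run first to pick the ensemble settings.
"""

from pathlib import Path

import pandas as pd

from healtheq import codebook as cb
from healtheq.data_model import load_survey
from healtheq.rf_importance import (ForestConfig, fit_forest, oob_importance,
                                    random_search)
from healtheq.univariate import chi2_screen

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2018


def main() -> None:
    table = load_survey(RESULTS / "synthetic_survey.csv")
    kept, _ = chi2_screen(table)
    X = table.df[kept]
    y = table.df[cb.OUTCOME].to_numpy()

    search = random_search(X, y, n_iter=8, k_folds=5, seed=SEED,
                           ranges={"n_estimators": (50, 200),
                                   "max_depth": (2, 20),
                                   "min_samples_split": (2, 20),
                                   "min_samples_leaf": (1, 10)})
    search.trials.to_csv(RESULTS / "forest_search_trials.csv", index=False)
    best = search.best_config
    print(f"search best CV accuracy {search.best_score:.4f} with "
          f"{best.n_estimators} trees, depth {best.max_depth}")

    cfg = ForestConfig(n_estimators=best.n_estimators, max_depth=best.max_depth,
                       min_samples_split=best.min_samples_split,
                       min_samples_leaf=best.min_samples_leaf, seed=SEED)
    forest = fit_forest(X, y, cfg)
    imp = oob_importance(forest, X, y, seed=SEED)
    imp.frame().to_csv(RESULTS / "importance.csv", index=False)
    print("\nOOB_store importance ranking (descending):")
    print(imp.frame().to_string(index=False))
    print("\nfactors with true generative effects should head the ranking")


if __name__ == "__main__":
    main()
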