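"""Bagged-tree fitting, OOB permutation importance, and randomized search."""

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score
from sklearn.ensemble import RandomForestClassifier

from healtheq import codebook as cb
from healtheq.data_model import DegenerateDataError
from healtheq.rf_importance import (ForestConfig, fit_forest, oob_importance,
                                    random_search)
from healtheq.synthetic import generate, study_config


def _toy(n=400, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    return rng, X


class TestFitForest:
    def test_separable_feature_gives_near_zero_oob_error(self):
        _, X = _toy()
        y = X[:, 0].copy()
        forest = fit_forest(X, y, ForestConfig(n_estimators=50, max_depth=3,
                                               mtry=4, seed=0))
        imp = oob_importance(forest, X, y, seed=0)
        assert np.mean(imp.err_oob1["x0"]) < 0.01

    def test_pure_noise_oob_error_matches_base_rate(self):
        rng, X = _toy(n=2_000, seed=1)
        mu = 0.3
        y = rng.binomial(1, mu, size=2_000)
        forest = fit_forest(X, y, ForestConfig(n_estimators=60, max_depth=2,
                                               mode="classification", seed=1))
        imp = oob_importance(forest, X, y, seed=1)
        base = np.mean([np.mean(v) for v in imp.err_oob1.values()])
        assert base == pytest.approx(min(mu, 1 - mu), abs=0.05)

    def test_fixed_seed_is_deterministic(self):
        rng, X = _toy(seed=2)
        y = rng.integers(0, 2, 400)
        cfg = ForestConfig(n_estimators=30, seed=5)
        a = oob_importance(fit_forest(X, y, cfg), X, y, seed=5)
        b = oob_importance(fit_forest(X, y, cfg), X, y, seed=5)
        assert a.oob_store == b.oob_store

    def test_single_class_outcome_rejected(self):
        _, X = _toy()
        with pytest.raises(DegenerateDataError, match="single class"):
            fit_forest(X, np.ones(400), ForestConfig())

    def test_config_ranges_enforced(self):
        with pytest.raises(ValueError, match="n_estimators"):
            ForestConfig(n_estimators=0).validate()
        with pytest.raises(ValueError, match="max_depth"):
            ForestConfig(max_depth=40).validate()


class TestOobImportance:
    def test_score_definition_matches_literal_per_tree_loop(self):
        rng, X = _toy(n=600, seed=3)
        y = (X[:, 0] + rng.random(600) > 0.8).astype(float)
        forest = fit_forest(X, y, ForestConfig(n_estimators=40, seed=3))
        imp = oob_importance(forest, X, y, seed=3)
        for f in imp.feature_names:
            n = imp.n_trees
            literal = sum(float(imp.err_oob2[f][i] - imp.err_oob1[f][i])
                          for i in range(n)) / n
            assert imp.oob_store[f] == pytest.approx(literal, abs=1e-15)
            assert len(imp.err_oob1[f]) == len(imp.err_oob2[f]) == n

    def test_feature_equal_to_outcome_ranks_first(self):
        wins = 0
        for seed in range(20):
            rng, X = _toy(n=300, seed=100 + seed)
            y = X[:, 1].copy()
            forest = fit_forest(X, y, ForestConfig(n_estimators=40, max_depth=4,
                                                   mtry=4, seed=seed))
            imp = oob_importance(forest, X, y, seed=seed)
            wins += imp.ranking[0] == "x1"
        assert wins >= 19

    def test_independent_feature_score_within_its_null_distribution(self):
        rng, X = _toy(n=800, seed=4)
        y = (X[:, 0] + 0.5 * rng.random(800) > 0.9).astype(float)
        forest = fit_forest(X, y, ForestConfig(n_estimators=50, seed=4))
        obs = oob_importance(forest, X, y, seed=0).oob_store["x3"]
        null = [abs(oob_importance(forest, X, y, seed=s).oob_store["x3"])
                for s in range(1, 40)]
        assert abs(obs) <= np.quantile(null, 0.975) + 1e-9

    def test_duplicated_feature_does_not_promote_noise(self):
        rng = np.random.default_rng(6)
        n = 800
        signal = rng.integers(0, 2, n).astype(float)
        noise = rng.integers(0, 2, n).astype(float)
        y = (signal + 0.3 * rng.random(n) > 0.6).astype(float)
        X = np.column_stack([signal, signal, noise])
        forest = fit_forest(X, y, ForestConfig(n_estimators=60, mtry=3, seed=6))
        imp = oob_importance(forest, X, y, seed=6)
        copies_mean = (imp.oob_store["x0"] + imp.oob_store["x1"]) / 2
        assert imp.oob_store["x2"] < copies_mean

    def test_study_conditions_rank_signal_above_noise(self):
        # income & education carry true effects; several factors are null
        noise = ["family_doctor", "insurance_location", "sick", "marital",
                 "working", "hukou", "health_level"]
        wins = 0
        for seed in range(20):
            table, _ = generate(study_config(n=4_000, seed=600 + seed))
            X = table.df[cb.FACTORS]
            y = table.df[cb.OUTCOME].to_numpy()
            forest = fit_forest(X, y, ForestConfig(n_estimators=100, max_depth=8,
                                                   seed=seed))
            imp = oob_importance(forest, X, y, seed=seed)
            best_noise = max(imp.oob_store[f] for f in noise)
            wins += (imp.oob_store["income_quintile"] > best_noise
                     and imp.oob_store["education"] > best_noise)
        assert wins >= 18


class TestRandomSearch:
    def test_single_iteration_returns_its_draw(self):
        rng, X = _toy(n=200, seed=7)
        y = rng.integers(0, 2, 200)
        res = random_search(X, y, n_iter=1, k_folds=3, seed=7)
        assert len(res.trials) == 1
        res.best_config.validate()

    def test_separable_data_reaches_perfect_cv_accuracy(self):
        _, X = _toy(n=200, seed=8)
        y = X[:, 0].astype(int)
        res = random_search(X, y, ranges={"n_estimators": (20, 30),
                                          "max_depth": (3, 6),
                                          "min_samples_split": (2, 4),
                                          "min_samples_leaf": (1, 2)},
                            n_iter=3, k_folds=3, seed=8)
        assert res.best_score == pytest.approx(1.0)

    def test_best_score_matches_independent_refit_on_same_folds(self, small_survey):
        X = small_survey.df[cb.FACTORS]
        y = small_survey.df[cb.OUTCOME].to_numpy()
        res = random_search(X, y, n_iter=3, k_folds=3, seed=9,
                            ranges={"n_estimators": (10, 40),
                                    "max_depth": (2, 8),
                                    "min_samples_split": (2, 10),
                                    "min_samples_leaf": (1, 5)})
        cfg = res.best_config
        clf = RandomForestClassifier(n_estimators=cfg.n_estimators,
                                     max_depth=cfg.max_depth,
                                     min_samples_split=cfg.min_samples_split,
                                     min_samples_leaf=cfg.min_samples_leaf,
                                     random_state=9)
        refit = cross_val_score(clf, X.to_numpy(float), y, cv=res.cv,
                                scoring="accuracy").mean()
        assert refit == pytest.approx(res.best_score, abs=1e-12)
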