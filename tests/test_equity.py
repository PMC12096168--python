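"""Fractional ranks, concentration index/curve, and Wagstaff decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from healtheq import codebook as cb
from healtheq.data_model import dummy_encode
from healtheq.equity import (concentration_curve_points, concentration_index,
                             curve_signed_area, erreygers_correct,
                             fractional_rank, wagstaff_decompose)
from healtheq.logit_model import fit_logit
from healtheq.synthetic import GeneratorConfig, generate


class TestFractionalRank:
    def test_midpoint_formula_three_values(self):
        rv = fractional_rank([10.0, 20.0, 30.0])
        np.testing.assert_allclose(rv.r, [1 / 6, 3 / 6, 5 / 6])

    def test_full_tie_gives_half(self):
        rv = fractional_rank(np.full(7, 3.0))
        np.testing.assert_allclose(rv.r, 0.5)

    def test_matches_brute_force_cumulative_weights(self):
        rng = np.random.default_rng(1)
        inc = rng.choice(rng.uniform(0, 100, 50), size=200)  # with ties
        w = rng.uniform(0.5, 2.0, 200)
        rv = fractional_rank(inc, w)
        total = w.sum()
        for i in range(200):
            below = w[inc < inc[i]].sum()
            tied = w[inc == inc[i]].sum()
            assert rv.r[i] == pytest.approx((below + tied / 2) / total, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_weighted_mean_rank_is_half(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 200)
        inc = rng.choice([1.0, 2.0, 5.0, 5.0, 9.0], size=n)
        w = rng.uniform(0.1, 3.0, n)
        rv = fractional_rank(inc, w)
        assert np.dot(rv.weights, rv.r) / rv.weights.sum() == pytest.approx(0.5)
        assert np.all((rv.r > 0) & (rv.r < 1))

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fractional_rank([])
        with pytest.raises(ValueError):
            fractional_rank([1.0, np.inf])


class TestConcentrationIndex:
    def test_constant_outcome_gives_zero(self):
        rv = fractional_rank(np.arange(10.0))
        res = concentration_index(np.ones(10), rv)
        assert res.ci == pytest.approx(0.0, abs=1e-15)
        assert res.direction == "neutral"

    def test_top_half_outcome_gives_plus_half(self):
        rv = fractional_rank(np.array([1.0, 2.0, 3.0, 4.0]))
        res = concentration_index(np.array([0.0, 0.0, 1.0, 1.0]), rv)
        assert res.ci == pytest.approx(0.5)
        assert res.direction == "pro-rich"

    def test_anti_sorted_outcome_is_pro_poor(self):
        rng = np.random.default_rng(2)
        inc = np.sort(rng.uniform(1, 100, 50))
        y = np.linspace(1, 0, 50)  # richer -> less outcome
        res = concentration_index(y, fractional_rank(inc))
        assert res.ci < 0
        assert res.direction == "pro-poor"

    def test_zero_mean_outcome_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            concentration_index(np.zeros(5), fractional_rank(np.arange(5.0)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_to_positive_income_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        inc = rng.lognormal(8, 1, 100)
        y = rng.binomial(1, 0.6, 100).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        a = concentration_index(y, fractional_rank(inc)).ci
        b = concentration_index(y, fractional_rank(inc * scale)).ci
        assert a == pytest.approx(b, abs=1e-12)

    def test_binary_bound_one_minus_mu(self):
        rng = np.random.default_rng(3)
        n = 5_000
        inc = rng.uniform(0, 1, n)
        rv = fractional_rank(inc)
        order = np.argsort(inc)
        for mu in np.arange(0.1, 0.95, 0.1):
            k = int(round(mu * n))
            y = np.zeros(n); y[order[-k:]] = 1.0   # adversarial pro-rich
            assert abs(concentration_index(y, rv).ci) <= 1 - y.mean() + 1e-9
            y_rand = rng.binomial(1, mu, n).astype(float)
            assert abs(concentration_index(y_rand, rv).ci) <= 1 - y_rand.mean()

    def test_erreygers_option_scales_by_four_mu(self):
        rv = fractional_rank(np.arange(8.0))
        res = concentration_index(np.array([0, 0, 0, 0, 1, 1, 1, 1.0]), rv)
        assert erreygers_correct(res) == pytest.approx(4 * res.mu * res.ci)


class TestConcentrationCurve:
    def test_constant_outcome_curve_is_diagonal(self):
        rv = fractional_rank(np.arange(20.0))
        curve = concentration_curve_points(np.ones(20), rv)
        np.testing.assert_allclose(curve[:, 0], curve[:, 1], atol=1e-12)

    def test_pro_rich_curve_below_diagonal(self):
        rv = fractional_rank(np.arange(100.0))
        y = (np.arange(100) >= 60).astype(float)
        curve = concentration_curve_points(y, rv)
        interior = curve[1:-1]
        assert np.all(interior[:, 1] <= interior[:, 0] + 1e-12)
        assert curve[0].tolist() == [0.0, 0.0]
        np.testing.assert_allclose(curve[-1], [1.0, 1.0])

    def test_twice_signed_area_approximates_index(self):
        rng = np.random.default_rng(4)
        n = 10_000
        inc = rng.lognormal(8, 1, n)
        rv = fractional_rank(inc)
        y = rng.binomial(1, 0.3 + 0.4 * rv.r).astype(float)
        res = concentration_index(y, rv)
        assert 2 * curve_signed_area(res.curve) == pytest.approx(res.ci, abs=1e-3)


class TestWagstaffDecomposition:
    def _decompose(self, table):
        X = dummy_encode(table)
        y = table.df[cb.OUTCOME].to_numpy()
        fit = fit_logit(X, y)
        ranks = fractional_rank(table.df[cb.INCOME_RAW].to_numpy())
        return wagstaff_decompose(fit, X, ranks, y), fit

    def test_identity_closes_to_machine_precision(self, medium_survey):
        table, _ = medium_survey
        decomp, _ = self._decompose(table)
        gap = decomp.total_ci - (decomp.explained() + decomp.residual_term)
        assert abs(gap) < 1e-12

    def test_null_model_contributions_vanish(self):
        cfg = GeneratorConfig(n=20_000, seed=5, true_beta={}, beta0=0.6)
        table, _ = generate(cfg)
        decomp, _ = self._decompose(table)
        assert abs(decomp.total_ci) < 4 / np.sqrt(20_000)
        assert decomp.table["contribution"].abs().max() < 0.01

    def test_income_only_truth_attributed_to_income(self):
        wins = 0
        betas = {"income_quintile_2": 0.3, "income_quintile_3": 0.5,
                 "income_quintile_4": 0.8, "income_quintile_5": 1.0}
        for seed in range(20):
            cfg = GeneratorConfig(n=20_000, seed=300 + seed,
                                  true_beta=dict(betas))
            table, _ = generate(cfg)
            decomp, _ = self._decompose(table)
            t = decomp.table
            income = t["column"].str.startswith("income_quintile")
            share = (t.loc[income, "contribution"].abs().sum()
                     / t["contribution"].abs().sum())
            wins += share >= 0.9
        assert wins >= 18

    def test_elasticity_and_rate_definitions(self, medium_survey):
        table, _ = medium_survey
        decomp, fit = self._decompose(table)
        row = decomp.table.iloc[0]
        assert row["elasticity"] == pytest.approx(
            row["ame"] * row["mean"] / decomp.mu)
        assert row["contribution"] == pytest.approx(
            row["elasticity"] * row["factor_ci"])
        assert row["rate"] == pytest.approx(
            row["contribution"] / decomp.total_ci * 100)
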