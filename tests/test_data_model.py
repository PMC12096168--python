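"""Data model: file round-trips, validation, cleaning, within-province
income quintiles, and dummy encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from healtheq import codebook as cb
from healtheq.data_model import (CleaningRules, SchemaError, SurveyTable,
                                 ValidationError, assign_income_quintiles,
                                 clean, dummy_encode, load_survey, write_survey)
from healtheq.synthetic import generate, study_config

from conftest import full_rows, make_table


class TestLoadSurvey:
    def test_round_trip_small_fixture(self, tmp_path):
        table = make_table(full_rows(3))
        path = tmp_path / "t.csv"
        write_survey(table, path)
        back = load_survey(path)
        assert back.n == 3
        pd.testing.assert_frame_equal(
            back.df[sorted(back.df.columns)], table.df[sorted(table.df.columns)],
            check_dtype=False)

    def test_out_of_code_value_names_row_and_field(self, tmp_path):
        rows = full_rows(3)
        rows["gender"] = np.array([0, 7, 1])
        write_survey(make_table(rows), tmp_path / "bad.csv")
        with pytest.raises(ValidationError, match=r"row 1.*gender"):
            load_survey(tmp_path / "bad.csv")

    def test_missing_column_is_schema_error(self, tmp_path):
        rows = full_rows(3)
        del rows["gender"]
        make_table(rows).df.to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(SchemaError, match="gender"):
            load_survey(tmp_path / "m.csv")

    def test_generated_file_round_trips_identically(self, tmp_path):
        table, _ = generate(study_config(n=1_000, seed=3))
        path = tmp_path / "gen.csv"
        write_survey(table, path)
        back = load_survey(path)
        for col in cb.FACTORS + [cb.OUTCOME, cb.PROVINCE]:
            assert (back.df[col].to_numpy() == table.df[col].to_numpy()).all()
        np.testing.assert_allclose(back.df[cb.INCOME_RAW], table.df[cb.INCOME_RAW])

    def test_tsv_delimiter_sniffed(self, tmp_path):
        table = make_table(full_rows(5))
        table.df.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        assert load_survey(tmp_path / "t.tsv").n == 5


class TestClean:
    def test_clean_table_unchanged_report_zero(self):
        table = make_table(full_rows(50))
        out, report = clean(table, CleaningRules(income_upper_quantile=None))
        assert out.n == 50
        assert all(v == 0 for v in report.values())

    def test_missing_outcome_rows_dropped_and_counted(self):
        rows = full_rows(10)
        y = rows[cb.OUTCOME].astype(float)
        y[[1, 4, 7]] = np.nan
        rows[cb.OUTCOME] = y
        out, report = clean(make_table(rows),
                            CleaningRules(income_upper_quantile=None))
        assert out.n == 7
        assert report["missing_required"] == 3

    def test_masked_rows_match_brute_force_count(self):
        rng = np.random.default_rng(42)
        rows = full_rows(1_000, seed=42)
        df = pd.DataFrame(rows).astype(float)
        mask = rng.random(df.shape) < 0.05
        df = df.mask(mask)
        df[cb.PROVINCE] = rows[cb.PROVINCE]  # keep grouping key intact
        expected = int(df.drop(columns=[]).notna().all(axis=1).sum())
        out, _ = clean(SurveyTable(df), CleaningRules(income_positive=False,
                                                      income_upper_quantile=None))
        assert out.n == expected

    def test_empty_result_raises(self):
        rows = full_rows(4)
        rows[cb.INCOME_RAW] = np.zeros(4)
        with pytest.raises(Exception, match="every row"):
            clean(make_table(rows))


class TestIncomeQuintiles:
    def test_distinct_incomes_fall_in_printed_bands(self):
        rows = full_rows(100)
        rows[cb.INCOME_RAW] = np.arange(1, 101, dtype=float)
        rows[cb.PROVINCE] = np.ones(100, dtype=int)
        out = assign_income_quintiles(make_table(rows))
        q = out.df.set_index(out.df[cb.INCOME_RAW].astype(int))["income_quintile"]
        assert (q.loc[1:19] == 1).all()
        assert (q.loc[20:39] == 2).all()
        assert (q.loc[40:59] == 3).all()
        assert (q.loc[60:79] == 4).all()
        assert (q.loc[80:100] == 5).all()

    def test_all_equal_incomes_share_one_band(self):
        rows = full_rows(30)
        rows[cb.INCOME_RAW] = np.full(30, 500.0)
        rows[cb.PROVINCE] = np.ones(30, dtype=int)
        out = assign_income_quintiles(make_table(rows))
        assert out.df["income_quintile"].nunique() == 1

    def test_matches_per_province_sort_and_cut_oracle(self):
        rng = np.random.default_rng(5)
        n = 400
        rows = full_rows(n, seed=5)
        rows[cb.PROVINCE] = rng.integers(1, 3, size=n)
        rows[cb.INCOME_RAW] = np.where(rows[cb.PROVINCE] == 1,
                                       rng.lognormal(8, 1, n),
                                       rng.lognormal(9, 1, n))
        out = assign_income_quintiles(make_table(rows))
        df = out.df
        for prov, g in df.groupby(cb.PROVINCE):
            inc = g[cb.INCOME_RAW].to_numpy()
            m = len(inc)
            for i in range(m):
                pct = np.sum(inc <= inc[i]) / m  # max-rank percentile
                expected = 1 + sum(pct >= e - 1e-12 for e in (0.2, 0.4, 0.6, 0.8))
                assert g["income_quintile"].iloc[i] == expected

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_to_monotone_income_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        rows = full_rows(n, seed=seed)
        rows[cb.INCOME_RAW] = rng.lognormal(8, 1, n)
        a = assign_income_quintiles(make_table(rows)).df["income_quintile"]
        rows2 = dict(rows)
        rows2[cb.INCOME_RAW] = np.log(rows[cb.INCOME_RAW]) * 3.7 + 1.0
        b = assign_income_quintiles(make_table(rows2)).df["income_quintile"]
        assert (a.to_numpy() == b.to_numpy()).all()


class TestDummyEncode:
    def test_three_level_factor_yields_two_columns(self, small_survey):
        X = dummy_encode(small_survey, ["mobility_range"], {"mobility_range": 1})
        assert X.slope_names() == ["mobility_range_2", "mobility_range_3"]

    def test_single_level_factor_warns_and_emits_nothing(self):
        rows = full_rows(20)
        rows["hukou"] = np.ones(20, dtype=int)
        with pytest.warns(UserWarning, match="single observed level"):
            X = dummy_encode(make_table(rows), ["hukou"], {"hukou": 1})
        assert X.slope_names() == []

    def test_model_factor_layout_matches_published_rows(self, small_survey):
        X = dummy_encode(small_survey)
        # 4 income + 3 age + 4 education + 1 record + 2 range + 2 reason + 1 gender
        assert len(X.slope_names()) == 17
        assert X.slope_names()[0] == "income_quintile_2"
        assert X.slope_names()[-1] == "gender_1"
        assert X.reference_groups == {f: 1 if min(cb.CODE_SETS[f]) == 1 else 0
                                      for f in cb.MODEL_FACTORS}

    def test_factor_block_row_sums(self, small_survey):
        X = dummy_encode(small_survey)
        df = small_survey.df
        for f in cb.MODEL_FACTORS:
            block = [j for j, n in enumerate(X.column_names)
                     if X.factor_of_column.get(n) == f]
            sums = X.values[:, block].sum(axis=1)
            is_ref = (df[f] == X.reference_groups[f]).to_numpy()
            assert ((sums <= 1) & (sums >= 0)).all()
            np.testing.assert_array_equal(sums, 1.0 - is_ref)

    def test_unknown_reference_level_rejected(self, small_survey):
        with pytest.raises(ValueError, match="reference level"):
            dummy_encode(small_survey, ["gender"], {"gender": 9})
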