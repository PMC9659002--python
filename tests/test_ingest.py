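"""Ingestion, crude rates and quintile risk-level classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fim_riskweight import (
    LCM,
    RISK_FACTORS,
    SchemaError,
    ValidationError,
    crude_rates,
    generate,
    level_frequencies,
    quintile_classify,
    read_mortality_table,
)
from fim_riskweight.ingest import brute_force_quintiles


def _long_rows(country, year, deaths=50.0, population=1e6):
    return [
        {"country": country, "year": year, "variable": v, "deaths": deaths,
         "population": population}
        for v in list(RISK_FACTORS) + [LCM]
    ]


class TestReadMortalityTable:
    def test_counts_all_valid_rows(self, tmp_path):
        df = pd.DataFrame(_long_rows("A", 2006) + _long_rows("B", 2006))
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = read_mortality_table(path)
        assert len(table) == 62  # 2 countries x 1 year x 31 variables

    def test_zero_population_identifies_row(self, tmp_path):
        rows = _long_rows("A", 2006)
        rows[4]["population"] = 0
        path = tmp_path / "t.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="population"):
            read_mortality_table(path)

    def test_negative_deaths_rejected(self, tmp_path):
        rows = _long_rows("A", 2006)
        rows[0]["deaths"] = -1
        path = tmp_path / "t.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="deaths"):
            read_mortality_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(_long_rows("A", 2006)).drop(columns="deaths").to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError):
            read_mortality_table(path)

    def test_schema_mapping_renames_columns(self, tmp_path):
        df = pd.DataFrame(_long_rows("A", 2006)).rename(
            columns={"country": "location_name"}
        )
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = read_mortality_table(path, schema={"country": "location_name"})
        assert set(table.columns) == {"country", "year", "variable", "deaths",
                                      "population"}

    def test_generator_output_round_trips(self, small_sim, tmp_path):
        _, table, _ = small_sim
        path = tmp_path / "sim.csv"
        table.to_csv(path, index=False)
        back = read_mortality_table(path)
        pd.testing.assert_frame_equal(
            back.sort_index(axis=1), table.sort_index(axis=1), check_dtype=False
        )


class TestCrudeRates:
    def test_single_year_division(self):
        table = pd.DataFrame(_long_rows("A", 2006, deaths=50, population=1_000_000)
                             + _long_rows("B", 2006))
        rates = crude_rates(table, unit="country-year")
        assert rates.loc[("A", 2006), "DB"] == pytest.approx(5e-5)

    def test_country_unit_averages_years(self):
        table = pd.DataFrame(
            _long_rows("A", 2006, deaths=40, population=1e6)
            + _long_rows("A", 2007, deaths=60, population=1e6)
        )
        rates = crude_rates(table, unit="country")
        assert rates.loc["A", "Smoking"] == pytest.approx(5e-5)

    def test_row_count_tracks_generator_bookkeeping(self, small_sim):
        cfg, table, _ = small_sim
        rates = crude_rates(table, unit="country-year")
        assert len(rates) == cfg.n_countries * cfg.n_years - cfg.missing_rows

    def test_unknown_unit_rejected(self, small_sim):
        _, table, _ = small_sim
        with pytest.raises(ValueError, match="unit"):
            crude_rates(table, unit="continent")


class TestQuintileClassify:
    def test_five_distinct_values_one_per_level(self):
        rates = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        assert quintile_classify(rates)["x"].tolist() == [1, 2, 3, 4, 5]

    def test_ten_ascending_values_pair_per_level(self):
        rates = pd.DataFrame({"x": np.arange(10.0)})
        assert quintile_classify(rates)["x"].tolist() == [
            1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_balance_at_study_size(self):
        # 1097 observations split into near-equal quintile groups
        rng = np.random.default_rng(0)
        rates = pd.DataFrame({"x": rng.random(1097)})
        freq = level_frequencies(quintile_classify(rates), "x")
        assert freq.sum() == 1097
        assert freq.max() - freq.min() <= 2
        assert sorted(freq) == [219, 219, 219, 220, 220]

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            quintile_classify(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))

    def test_constant_column_all_level_one(self, caplog):
        rates = pd.DataFrame({"x": np.ones(10)})
        with caplog.at_level("WARNING"):
            levels = quintile_classify(rates)
        assert (levels["x"] == 1).all()
        assert "constant" in caplog.text

    def test_monotone_in_rate(self):
        rng = np.random.default_rng(1)
        x = rng.random(57)
        lv = quintile_classify(pd.DataFrame({"x": x}))["x"].to_numpy()
        order = np.argsort(x)
        assert (np.diff(lv[order]) >= 0).all()

    @given(st.lists(st.integers(0, 200), min_size=5, max_size=60).filter(
        lambda v: len(set(v)) > 1))  # constant columns follow their own contract
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_matches_brute_force_oracle(self, values):
        rates = pd.DataFrame({"x": np.asarray(values, dtype=float)})
        got = quintile_classify(rates)["x"].to_numpy()
        expected = brute_force_quintiles(values)
        assert (got == expected).all()

    def test_scale_invariance(self):
        # scaling all of a variable's deaths leaves its level column unchanged
        rng = np.random.default_rng(2)
        x = rng.random(40)
        a = quintile_classify(pd.DataFrame({"x": x}))
        b = quintile_classify(pd.DataFrame({"x": 7.3 * x}))
        pd.testing.assert_frame_equal(a, b)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.random(40)
        perm = rng.permutation(40)
        base = quintile_classify(pd.DataFrame({"x": x}))["x"].to_numpy()
        permuted = quintile_classify(pd.DataFrame({"x": x[perm]}))["x"].to_numpy()
        assert (permuted == base[perm]).all()


class TestLevelFrequencies:
    def test_one_per_level(self):
        levels = pd.DataFrame({"x": [1, 2, 3, 4, 5]})
        assert level_frequencies(levels, "x").tolist() == [1, 1, 1, 1, 1]

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            level_frequencies(pd.DataFrame({"x": [1, 2, 3]}), "y")

    def test_sums_to_observation_count(self, default_matrices):
        _, levels = default_matrices
        freq = level_frequencies(levels, LCM)
        assert freq.sum() == len(levels) == 1097
        assert freq.max() - freq.min() <= 2
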