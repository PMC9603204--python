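"""Stock/sink identities, aggregation, and the published summary statistics."""

import numpy as np
import pandas as pd
import pytest

from arborcarbon.accounting import (
    aggregate,
    annual_sink,
    carbon_stock,
    cumulative_and_average,
    growth_statistics,
    round_reported,
)
from arborcarbon.parameters import packaged_data_path


def series_frame(c_by_year, species="X", fc="public_welfare", area=2.0):
    years = sorted(c_by_year)
    return pd.DataFrame(
        {
            "species": species,
            "forest_class": fc,
            "year": years,
            "A": area,
            "D": [c_by_year[y] / area for y in years],
            "C": [c_by_year[y] for y in years],
        }
    )


class TestCarbonStock:
    def test_zero_density_zero_stock(self):
        assert carbon_stock(0.0, 123.4) == 0.0

    def test_unit_identity(self):
        # MgC/ha x Mha = MtC with no conversion factor
        assert carbon_stock(50.0, 2.0) == 100.0

    def test_published_2018_product(self):
        # density rounded to one decimal explains the small gap to 7344.8
        assert carbon_stock(40.8, 179.9) == pytest.approx(7344.8, abs=0.05 * 179.9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            carbon_stock(-1.0, 1.0)


class TestAnnualSink:
    def test_constant_stock_gives_zero_sinks(self):
        out = annual_sink(series_frame({2018: 5.0, 2019: 5.0, 2020: 5.0}))
        assert out["S"].iloc[0] != out["S"].iloc[0]  # first year NaN
        assert (out["S"].iloc[1:] == 0.0).all()

    def test_recovers_constructed_increments(self):
        increments = [3.0, -1.5, 0.25, 7.0]
        c = dict(zip(range(2018, 2023), np.cumsum([10.0] + increments)))
        out = annual_sink(series_frame(c))
        assert out["S"].iloc[1:].tolist() == pytest.approx(increments)

    def test_year_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            annual_sink(series_frame({2018: 1.0, 2020: 2.0}))


class TestCumulativeAndAverage:
    def test_existing_forest_window(self):
        c = pd.Series({2018: 7344.8, 2060: 14516.4}).reindex(range(2018, 2061)).interpolate()
        cum, avg = cumulative_and_average(c, 2019, 2060)
        assert cum == pytest.approx(7171.6, abs=1e-9)
        assert round_reported(7171.5 / 42) == 170.8

    def test_published_averages_over_42_years(self):
        assert round_reported(7171.5 / 42) == 170.8
        assert round_reported(13785.5 / 42) == 328.2

    def test_single_year_window_is_that_sink(self):
        c = pd.Series({2018: 10.0, 2019: 12.5, 2020: 16.0})
        cum, avg = cumulative_and_average(c, 2019, 2019)
        assert cum == avg == pytest.approx(2.5)

    def test_window_equals_sum_of_annual_sinks(self, pwf_run):
        nat = aggregate(pwf_run["stocks"], "national").set_index("year")
        cum, _ = cumulative_and_average(nat["C"], 2019, 2060)
        assert cum == pytest.approx(nat["C"].diff().loc[2019:2060].sum(), abs=1e-9)

    def test_out_of_horizon_rejected(self):
        with pytest.raises(ValueError):
            cumulative_and_average(pd.Series({2018: 1.0, 2019: 2.0}), 2019, 2060)


class TestGrowthStatistics:
    def test_published_19_species_growth(self):
        pct, rate = growth_statistics(6876.9, 13591.6, 42)
        assert round_reported(pct) == 97.6
        assert round_reported(rate, 2) == 1.64

    def test_no_growth_is_zero(self):
        assert growth_statistics(100.0, 100.0, 10) == (0.0, 0.0)

    def test_doubling_in_ten_years(self):
        pct, rate = growth_statistics(100.0, 200.0, 10)
        assert pct == pytest.approx(100.0)
        assert rate == pytest.approx((2 ** 0.1 - 1) * 100, abs=1e-9)
        assert round_reported(rate, 2) == 7.18

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError):
            growth_statistics(0.0, 10.0, 5)


@pytest.fixture(scope="module")
def table4():
    return pd.read_csv(packaged_data_path("cumulative_sinks_2019_2060.csv"), comment="#")


class TestAggregate:

    def test_published_class_columns_sum(self, table4):
        assert table4["public_welfare_MtC"].sum() == pytest.approx(5215.6, abs=0.95)
        assert table4["commercial_MtC"].sum() == pytest.approx(1499.1, abs=0.95)

    def test_negative_cumulative_sinks_not_clipped(self, table4):
        fir = table4.set_index("species").loc["Fir"]
        assert fir["commercial_MtC"] == -3.9

    def test_aggregate_of_single_series_is_itself(self):
        frame = series_frame({2018: 4.0, 2019: 6.0})
        out = aggregate(frame, "national")
        assert out["C"].tolist() == [4.0, 6.0]
        assert out["A"].tolist() == [2.0, 2.0]

    def test_aggregation_is_associative(self, pwf_run):
        stocks = pwf_run["stocks"]
        via_species = aggregate(aggregate(stocks, "species"), "national")
        direct = aggregate(stocks, "national")
        assert np.allclose(via_species["C"], direct["C"], atol=1e-9)
        assert np.allclose(via_species["A"], direct["A"], atol=1e-9)

    def test_aggregate_density_is_stock_over_area(self, pwf_run):
        nat = aggregate(pwf_run["stocks"], "national")
        assert np.allclose(nat["D"], nat["C"] / nat["A"])

    def test_simulated_series_satisfies_stock_identity(self, pwf_run):
        stocks = pwf_run["stocks"]
        assert np.allclose(stocks["C"], stocks["D"] * stocks["A"], atol=1e-9)
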