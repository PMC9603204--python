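"""Fuel-substitution calculus: avoided emissions of bioenergy vs coal."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborcarbon.bioenergy import (
    SubstitutionCase,
    emissions_alternative,
    emissions_substituted,
    make_coal_substitution_case,
    mitigation,
    mitigation_series,
)
from arborcarbon.parameters import GASES, FuelSpec


@pytest.fixture(scope="module")
def coal_ef(emission_factors):
    return emission_factors[("Coal", "Anthracite stoves")]


@pytest.fixture(scope="module")
def trad_ef(emission_factors):
    return emission_factors[("Forestry bioenergy", "Traditional cookstoves")]


def unit_case(stove, emission_factors, fi=1.0, **fuel_overrides):
    case = make_coal_substitution_case(stove, emission_factors, fi)
    if fuel_overrides:
        case = SubstitutionCase(
            substituted_fuel=fuel_overrides.get("coal", case.substituted_fuel),
            substituted_ef=case.substituted_ef,
            alternative_fuel=fuel_overrides.get("bio", case.alternative_fuel),
            alternative_ef=case.alternative_ef,
            fuel_input=fi,
        )
    return case


class TestEmissionEquations:
    def test_zero_fuel_zero_emissions(self, trad_ef):
        assert all(v == 0.0 for v in emissions_alternative(0.0, trad_ef).values())

    def test_traditional_stove_methane(self, trad_ef):
        # 1000 kg of biofuel in a traditional cookstove
        assert emissions_alternative(1000.0, trad_ef)["CH4"] == pytest.approx(9400.0)

    def test_bioenergy_co2_factor_is_zero(self, trad_ef, emission_factors):
        improved = emission_factors[("Forestry bioenergy", "Improved stoves")]
        assert emissions_alternative(1000.0, trad_ef)["CO2"] == 0.0
        assert emissions_alternative(1000.0, improved)["CO2"] == 0.0

    def test_unit_ratios_reduce_to_factor(self, coal_ef):
        e_s = emissions_substituted(1.0, 15.0, 15.0, 0.2, 0.2, coal_ef)
        assert e_s == pytest.approx({g: coal_ef.ef[g] for g in GASES})

    def test_equal_heat_coal_co2(self, coal_ef):
        e_s = emissions_substituted(1000.0, 15.0, 29.0, 0.25, 0.25, coal_ef)
        assert e_s["CO2"] == pytest.approx(1000.0 * (15.0 / 29.0) * 2876.26)
        assert e_s["CO2"] == pytest.approx(1487.7e3, rel=5e-5)

    def test_linear_in_efficiency_ratio(self, coal_ef):
        base = emissions_substituted(10.0, 15.0, 29.0, 0.15, 0.25, coal_ef)
        double = emissions_substituted(10.0, 15.0, 29.0, 0.30, 0.25, coal_ef)
        assert double == pytest.approx({g: 2 * v for g, v in base.items()})

    def test_zero_denominators_rejected(self, coal_ef):
        with pytest.raises(ValueError):
            emissions_substituted(1.0, 15.0, 0.0, 0.2, 0.2, coal_ef)


class TestMitigation:
    def test_zero_fuel_input_zero_everything(self, emission_factors):
        result = mitigation(unit_case("traditional", emission_factors, fi=0.0))
        assert all(v == 0.0 for v in result.per_gas.values())
        assert result.co2e == result.carbon_mass == 0.0

    def test_self_substitution_is_exactly_zero(self, coal_ef):
        fuel = FuelSpec(29.0, 0.25)
        case = SubstitutionCase(fuel, coal_ef, fuel, coal_ef, fuel_input=123.0)
        result = mitigation(case)
        assert all(v == 0.0 for v in result.per_gas.values())

    def test_methane_mitigation_negative_at_unit_ratios(self, coal_ef, trad_ef):
        # biomass stoves emit more CH4 per kg than coal stoves
        fuel = FuelSpec(15.0, 0.2)
        case = SubstitutionCase(fuel, coal_ef, fuel, trad_ef, fuel_input=1000.0)
        result = mitigation(case)
        assert result.per_gas["CH4"] == pytest.approx((8.78 - 9.4) * 1000.0)
        assert result.per_gas["CH4"] < 0

    def test_carbon_mass_is_co2e_times_12_over_44(self, emission_factors):
        result = mitigation(unit_case("improved", emission_factors, fi=500.0))
        assert result.carbon_mass == pytest.approx(result.co2e * 12.0 / 44.0)

    def test_co2_component_equals_substituted_emission(self, emission_factors):
        # bioenergy CO2 factor is zero, so mitigated CO2 = coal-side CO2
        case = unit_case("traditional", emission_factors, fi=1000.0)
        e_s = emissions_substituted(
            1000.0,
            case.alternative_fuel.energy_content,
            case.substituted_fuel.energy_content,
            case.alternative_fuel.efficiency,
            case.substituted_fuel.efficiency,
            case.substituted_ef,
        )
        assert mitigation(case).per_gas["CO2"] == pytest.approx(e_s["CO2"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(fi=st.floats(0.0, 1e6), alpha=st.floats(0.0, 100.0))
    def test_linearity_in_fuel_input(self, emission_factors, fi, alpha):
        base = mitigation(unit_case("traditional", emission_factors, fi=fi))
        scaled = mitigation(unit_case("traditional", emission_factors, fi=alpha * fi))
        for gas in GASES:
            assert scaled.per_gas[gas] == pytest.approx(
                alpha * base.per_gas[gas], rel=1e-12, abs=1e-9
            )

    def test_strictly_positive_co2_mitigation_for_positive_input(self, emission_factors):
        for stove in ("traditional", "improved"):
            for fi in (1e-6, 1.0, 1e9):
                assert mitigation(unit_case(stove, emission_factors, fi=fi)).per_gas["CO2"] > 0

    def test_carbon_mass_monotone_in_stove_efficiency(self, emission_factors):
        results = [
            mitigation(
                unit_case("traditional", emission_factors, fi=1000.0, bio=FuelSpec(15.0, eta))
            ).carbon_mass
            for eta in (0.10, 0.15, 0.25, 0.40)
        ]
        assert results == sorted(results)


class TestMitigationSeries:
    def test_no_harvest_means_zero_series(self, emission_factors):
        empty = pd.DataFrame(columns=["species", "year", "residue_carbon"])
        series = mitigation_series(empty, 0.47, "traditional", emission_factors,
                                   years=range(2019, 2061))
        assert (series == 0.0).all() and len(series) == 42

    def test_public_welfare_scenario_mitigates_nothing(self, pwf_run):
        for stove in ("traditional", "improved"):
            assert (pwf_run["mitigation"][(stove, "new")] == 0.0).all()

    def test_improved_stove_dominates_traditional_yearwise(self, commercial_run):
        for origin in ("existing", "new"):
            trad = commercial_run["mitigation"][("traditional", origin)]
            impr = commercial_run["mitigation"][("improved", origin)]
            assert (impr >= trad - 1e-12).all()

    def test_mean_times_horizon_equals_sum(self, commercial_run):
        series = commercial_run["mitigation"][("traditional", "existing")]
        assert series.mean() * 42 == pytest.approx(series.sum())

    def test_fuel_input_conversion_via_stem_carbon_fraction(self, emission_factors):
        flows = pd.DataFrame({"species": ["X"], "year": [2030], "residue_carbon": [1.0]})
        half = mitigation_series(flows, 0.5, "traditional", emission_factors)
        quarter = mitigation_series(flows, 0.25, "traditional", emission_factors)
        # halving the carbon fraction doubles the dry fuel mass
        assert quarter.loc[2030] == pytest.approx(2 * half.loc[2030])
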