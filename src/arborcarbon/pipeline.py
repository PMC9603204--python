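"""Pipeline orchestration, identity verification and report writing.

``run_pipeline`` chains the stages -- synthetic fixtures, cohort growth,
scenario assembly, stock/sink accounting, bioenergy substitution -- into
one deterministic run driven by a seed, and writes tidy CSV outputs plus
a JSON summary. ``verify_identities`` recomputes every internal
arithmetic identity of the published national tables (column sums, stock
differences, ratios, the afforestation schedule) and compares them with
the printed values at printed precision.

The simulated 19 dominant species cover 161.8 of the 179.9 Mha of arbor
forest; the published national accounting scales to all arbor forests by
a proportional remainder (its existing-forest stocks are exactly
7344.8/6876.9 times the 19-species stocks at printed precision). The
pipeline applies the same scaling when reporting all-arbor totals and
carries the 18.1 Mha remainder explicitly in area bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import accounting, bioenergy
from .accounting import round_reported
from .fixtures import (
    FixtureSpec,
    age_share_map,
    generate_age_structure,
    generate_growth_params,
    generate_management,
)
from .parameters import load_emission_factors, load_species_table, packaged_data_path
from .scenario import (
    ScenarioSpec,
    assemble_scenario,
    build_afforestation_schedule,
    simulate,
)

__all__ = ["RunConfig", "run_pipeline", "verify_identities", "load_config"]

#: Published scaling from the 19 dominant species to all arbor forests.
ALL_ARBOR_SCALE = 7344.8 / 6876.9


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Every stochastic choice routes through ``seed``. Scenario fields
    select the use class of new plantations and the stove technology of
    the substitution accounting; fixture fields override the synthetic
    generator's calibration spec.
    """

    seed: int = 0
    new_forest_class: str = "public_welfare"
    stove: str = "traditional"
    out_dir: str = "results/run"
    horizon: tuple[int, int] = (2018, 2060)
    land_area: float = 960.1
    coverage_now: float = 0.2296
    coverage_2035: float = 0.26
    coverage_2050: float = 0.307
    existing_forest_area: float = 220.5
    young_middle_share: float = 0.639
    ym_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def fixture_spec(self) -> FixtureSpec:
        return FixtureSpec(
            seed=self.seed,
            young_middle_share=self.young_middle_share,
            ym_overrides=dict(self.ym_overrides),
        )

    def scenario_spec(self) -> ScenarioSpec:
        return ScenarioSpec(
            new_forest_class=self.new_forest_class,
            horizon=tuple(self.horizon),
            stove=self.stove,
        )

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "log_level")}
        payload = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "horizon" in raw:
        raw["horizon"] = tuple(raw["horizon"])
    return RunConfig(**raw)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute fixtures -> growth -> scenario -> accounting -> bioenergy.

    Returns a dict with the tidy stock series (19 species, by use class
    and origin), harvest flows, per-stove mitigation series, benchmark
    scenario table and the summary statistics. With ``write=True`` all of
    it lands under ``config.out_dir`` together with a run log recording
    the seed and config hash.
    """
    y0, y1 = config.horizon
    spec = config.scenario_spec()
    fixture_spec = config.fixture_spec()

    stage = "parameters"
    try:
        records = load_species_table()
        emission_factors = load_emission_factors()

        stage = "fixtures"
        management = generate_management(fixture_spec, [r.name for r in records])
        params = generate_growth_params(fixture_spec, records, management)
        structures = {
            r.name: age_share_map(generate_age_structure(fixture_spec, r)) for r in records
        }

        stage = "scenario"
        areas_2018 = {r.name: r.total_area for r in records}
        plan = build_afforestation_schedule(
            existing_forest_area=config.existing_forest_area,
            coverage_now=config.coverage_now,
            coverage_2035=config.coverage_2035,
            coverage_2050=config.coverage_2050,
            land_area=config.land_area,
            species_weights={n: a / sum(areas_2018.values()) for n, a in areas_2018.items()},
        )
        scenario = assemble_scenario(spec, plan, records, params, management, structures)

        stage = "growth"
        stocks, harvests = simulate(scenario)

        stage = "accounting"
        stocks = accounting.annual_sink(stocks)
        existing = stocks[stocks["origin"] == "existing"]
        new = stocks[stocks["origin"] == "new"]
        nat_existing = accounting.national_stock(existing)
        nat_new = accounting.national_stock(new).reindex(range(y0, y1 + 1), fill_value=0.0)
        cum_existing, avg_existing = accounting.cumulative_and_average(nat_existing, y0 + 1, y1)
        densities = accounting.aggregate(existing, "species").set_index(["species", "year"])["D"]

        stage = "bioenergy"
        cf_stem = {r.name: r.carbon_fraction["stem"] for r in records}
        mitigation = {}
        for stove in ("traditional", "improved"):
            for origin in ("existing", "new"):
                flows = harvests[harvests["origin"] == origin]
                mitigation[(stove, origin)] = bioenergy.mitigation_series(
                    flows, cf_stem, stove, emission_factors, years=range(y0 + 1, y1 + 1)
                )

        stage = "report"
        scale = ALL_ARBOR_SCALE
        bench_years = [2018, 2020, 2030, 2040, 2050, 2060]
        nat_total = nat_existing * scale + nat_new
        bench = pd.DataFrame(
            {
                "year": bench_years,
                "area_Mha": [scenario.total_area(y) for y in bench_years],
                "stock_MtC": [nat_total.loc[y] for y in bench_years],
            }
        )
        bench["sink_MtC_per_a"] = [float("nan")] + [
            float(nat_total.loc[y] - nat_total.loc[y - 1]) for y in bench_years[1:]
        ]
        bench["density_MgC_per_ha"] = bench["stock_MtC"] / bench["area_Mha"]

        sink_by_class = accounting.aggregate(existing, "forest_class")
        cum_by_class = {
            fc: accounting.cumulative_and_average(
                sink_by_class[sink_by_class["forest_class"] == fc], y0 + 1, y1
            )
            for fc in ("public_welfare", "commercial")
        }
        species_cum = (
            existing.groupby(["species", "forest_class"])
            .apply(
                lambda g: accounting.cumulative_and_average(g, y0 + 1, y1)[0],
                include_groups=False,
            )
            .unstack("forest_class")
            .rename(
                columns={"public_welfare": "public_welfare_MtC", "commercial": "commercial_MtC"}
            )
        )
        species_cum["total_MtC"] = species_cum.sum(axis=1)

        d2018 = densities.xs(y0, level="year")
        d2060 = densities.xs(y1, level="year")
        cum_total, avg_total = accounting.cumulative_and_average(nat_total, y0 + 1, y1)
        summary = {
            "seed": config.seed,
            "config_digest": config.digest(),
            "scenario": spec.new_forest_class,
            "stock_19_species_2018_MtC": round(float(nat_existing.loc[y0]), 1),
            "stock_19_species_2060_MtC": round(float(nat_existing.loc[y1]), 1),
            "stock_existing_all_arbor_2018_MtC": round(float(nat_existing.loc[y0] * scale), 1),
            "stock_existing_all_arbor_2060_MtC": round(float(nat_existing.loc[y1] * scale), 1),
            "cumulative_sink_existing_MtC": round(cum_existing, 1),
            "mean_annual_sink_existing_MtC_per_a": round(avg_existing, 1),
            "cumulative_sink_existing_all_arbor_MtC": round(cum_existing * scale, 1),
            "mean_annual_sink_existing_all_arbor_MtC_per_a": round(avg_existing * scale, 1),
            "cumulative_sink_existing_pwf_MtC": round(cum_by_class["public_welfare"][0], 1),
            "cumulative_sink_existing_com_MtC": round(cum_by_class["commercial"][0], 1),
            "cumulative_sink_new_MtC": round(float(nat_new.loc[y1]), 1),
            "total_stock_2060_MtC": round(float(nat_total.loc[y1]), 1),
            "total_cumulative_sink_MtC": round(cum_total, 1),
            "total_mean_annual_sink_MtC_per_a": round(avg_total, 1),
            "area_2050_Mha": round(scenario.total_area(2050), 1),
            "density_2018_min_MgC_per_ha": round(float(d2018.min()), 1),
            "density_2018_max_MgC_per_ha": round(float(d2018.max()), 1),
            "density_2060_min_MgC_per_ha": round(float(d2060.min()), 1),
            "density_2060_max_MgC_per_ha": round(float(d2060.max()), 1),
        }
        for stove in ("traditional", "improved"):
            for origin in ("existing", "new"):
                series = mitigation[(stove, origin)]
                summary[f"cum_mitigation_{origin}_{stove}_MtC"] = round(float(series.sum()), 1)
                summary[f"avg_mitigation_{origin}_{stove}_MtC_per_a"] = round(
                    float(series.mean()), 1
                )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = {
        "stocks": stocks,
        "harvests": harvests,
        "mitigation": mitigation,
        "benchmark": bench,
        "species_cumulative": species_cum,
        "summary": summary,
    }
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stocks.to_csv(out / "stock_series.csv", index=False)
        harvests.to_csv(out / "harvest_flows.csv", index=False)
        mit = pd.DataFrame(
            {f"{stove}_{origin}": s for (stove, origin), s in mitigation.items()}
        )
        mit.to_csv(out / "mitigation_series.csv")
        bench.to_csv(out / "scenario_benchmarks.csv", index=False)
        species_cum.to_csv(out / "species_cumulative_sinks.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"seed={config.seed}\nconfig_digest={config.digest()}\n")
            fh.write(f"scenario={spec.new_forest_class}\nstove={config.stove}\n")
            fh.write(f"horizon={y0}-{y1}\ncohorts={len(scenario.cohorts)}\n")
    return result


# --------------------------------------------------------------------------
# identity verification against the published tables
# --------------------------------------------------------------------------

_N_SPECIES_TOL = 19 * 0.05  # printed one-decimal rounding per summand


def _identity_rows(tables: Mapping[str, pd.DataFrame]) -> list[tuple[str, float, float, float]]:
    rows: list[tuple[str, float, float, float]] = []
    stats = None
    if "reported_statistics" in tables:
        t = tables["reported_statistics"]
        stats = dict(zip(t["name"], t["value"].astype(float)))

    if "inventory_2018" in tables and stats:
        inv = tables["inventory_2018"]
        area = inv["area_public_welfare_Mha"].sum() + inv["area_commercial_Mha"].sum()
        rows += [
            ("inventory_total_volume_Mm3", float(inv["volume_Mm3"].sum()),
             stats["table1_total_volume_Mm3"], _N_SPECIES_TOL),
            ("inventory_total_area_Mha", float(area), stats["table1_total_area_Mha"], 2 * _N_SPECIES_TOL),
            ("dominant_area_share_pct", 100.0 * area / stats["arbor_area_2018_Mha"],
             stats["table1_area_share_pct"], 0.1),
        ]

    if stats:
        plan = build_afforestation_schedule(
            existing_forest_area=stats["forest_area_2018_Mha"],
            coverage_2035=stats["forest_coverage_2035_pct"] / 100.0,
            coverage_2050=stats["forest_coverage_2050_pct"] / 100.0,
        )
        rate_1 = plan.planted[2019]
        rate_2 = plan.planted[2040]
        pct, rate = accounting.growth_statistics(
            stats["stock_19_species_2018_MtC"], stats["stock_19_species_2060_MtC"], 42
        )
        pct_ex, _ = accounting.growth_statistics(
            stats["stock_existing_2018_MtC"], stats["stock_existing_2060_MtC"], 42
        )
        pct_com, _ = accounting.growth_statistics(
            stats["stock_existing_com_2018_MtC"], stats["stock_existing_com_2060_MtC"], 42
        )
        cum_ex = stats["stock_existing_2060_MtC"] - stats["stock_existing_2018_MtC"]
        rows += [
            ("afforestation_rate_2019_2035_Mha", round_reported(rate_1),
             stats["afforestation_rate_2019_2035_Mha"], 0.05),
            ("afforestation_rate_2036_2050_Mha", round_reported(rate_2),
             stats["afforestation_rate_2036_2050_Mha"], 0.05),
            ("arbor_area_2050_Mha", stats["arbor_area_2018_Mha"] + plan.cumulative_by(2050),
             stats["arbor_area_2050_Mha"], 0.05),
            ("stock_2018_density_times_area_MtC",
             accounting.carbon_stock(stats["density_existing_2018_MgC_per_ha"],
                                     stats["arbor_area_2018_Mha"]),
             stats["stock_existing_2018_MtC"], 0.05 * stats["arbor_area_2018_Mha"]),
            ("stock_2018_class_split_MtC",
             stats["stock_existing_pwf_2018_MtC"] + stats["stock_existing_com_2018_MtC"],
             stats["stock_existing_2018_MtC"], 0.15),
            ("share_pwf_2018_pct",
             100.0 * stats["stock_existing_pwf_2018_MtC"] / stats["stock_existing_2018_MtC"],
             stats["share_pwf_2018_pct"], 0.1),
            ("stock_growth_pct", pct, stats["stock_growth_pct"], 0.1),
            ("mean_annual_growth_rate_pct", rate, stats["mean_annual_growth_rate_pct"], 0.005),
            ("stock_growth_existing_pct", pct_ex, stats["stock_growth_pct"], 0.1),
            ("stock_growth_commercial_pct", pct_com, stats["com_growth_2018_2060_pct"], 0.1),
            ("cumulative_sink_existing_MtC", cum_ex, stats["cumulative_sink_existing_MtC"], 0.15),
            ("mean_annual_sink_existing_MtC_per_a", cum_ex / 42.0,
             stats["mean_annual_sink_existing_MtC_per_a"], 0.1),
            ("sink_class_split_MtC_per_a",
             stats["mean_annual_sink_existing_pwf_MtC_per_a"]
             + stats["mean_annual_sink_existing_com_MtC_per_a"],
             stats["mean_annual_sink_existing_MtC_per_a"], 0.15),
            ("avg_mitigation_existing_traditional_MtC_per_a",
             stats["cum_mitigation_existing_traditional_MtC"] / 42.0,
             stats["avg_mitigation_existing_traditional_MtC_per_a"], 0.05),
            ("avg_mitigation_existing_improved_MtC_per_a",
             stats["cum_mitigation_existing_improved_MtC"] / 42.0,
             stats["avg_mitigation_existing_improved_MtC_per_a"], 0.05),
            ("cum_sink_existing_plus_traditional_MtC",
             stats["cumulative_sink_existing_MtC"]
             + stats["cum_mitigation_existing_traditional_MtC"],
             stats["cum_sink_existing_plus_traditional_MtC"], 0.15),
            ("avg_sink_existing_plus_traditional_MtC_per_a",
             stats["cum_sink_existing_plus_traditional_MtC"] / 42.0,
             stats["avg_sink_existing_plus_traditional_MtC_per_a"], 0.1),
            ("pct_gain_traditional",
             100.0 * (stats["avg_sink_existing_plus_traditional_MtC_per_a"]
                      / stats["mean_annual_sink_existing_MtC_per_a"] - 1.0),
             stats["pct_gain_traditional"], 0.1),
            ("cum_sink_existing_plus_improved_MtC",
             stats["cumulative_sink_existing_MtC"] + stats["cum_mitigation_existing_improved_MtC"],
             stats["cum_sink_existing_plus_improved_MtC"], 0.15),
            ("avg_sink_existing_plus_improved_MtC_per_a",
             stats["cum_sink_existing_plus_improved_MtC"] / 42.0,
             stats["avg_sink_existing_plus_improved_MtC_per_a"], 0.1),
            ("pct_gain_improved",
             100.0 * (stats["avg_sink_existing_plus_improved_MtC_per_a"]
                      / stats["mean_annual_sink_existing_MtC_per_a"] - 1.0),
             stats["pct_gain_improved"], 0.1),
            ("cum_sink_new_com_plus_traditional_MtC",
             stats["cum_sink_new_com_MtC"] + stats["cum_mitigation_new_traditional_MtC"],
             stats["cum_sink_new_com_plus_traditional_MtC"], 0.15),
            ("cum_sink_new_com_plus_improved_MtC",
             stats["cum_sink_new_com_MtC"] + stats["cum_mitigation_new_improved_MtC"],
             stats["cum_sink_new_com_plus_improved_MtC"], 0.15),
            ("avg_mitigation_new_traditional_MtC_per_a",
             stats["cum_mitigation_new_traditional_MtC"] / 42.0,
             stats["avg_mitigation_new_traditional_MtC_per_a"], 0.05),
            ("avg_mitigation_new_improved_MtC_per_a",
             stats["cum_mitigation_new_improved_MtC"] / 42.0,
             stats["avg_mitigation_new_improved_MtC_per_a"], 0.05),
        ]

    if "cumulative_sinks_2019_2060" in tables and stats:
        t4 = tables["cumulative_sinks_2019_2060"]
        row_gap = (t4["public_welfare_MtC"] + t4["commercial_MtC"] - t4["total_MtC"]).abs().max()
        rows += [
            ("cumulative_sink_pwf_sum_MtC", float(t4["public_welfare_MtC"].sum()),
             stats["table4_total_pwf_MtC"], _N_SPECIES_TOL),
            ("cumulative_sink_com_sum_MtC", float(t4["commercial_MtC"].sum()),
             stats["table4_total_com_MtC"], _N_SPECIES_TOL),
            ("cumulative_sink_total_sum_MtC", float(t4["total_MtC"].sum()),
             stats["table4_total_MtC"], _N_SPECIES_TOL),
            ("cumulative_sink_class_split_MtC",
             stats["table4_total_pwf_MtC"] + stats["table4_total_com_MtC"],
             stats["table4_total_MtC"], 0.05),
            ("cumulative_sink_row_consistency_MtC", float(row_gap), 0.0, 0.15),
        ]

    if "scenario_summary" in tables and stats:
        t5 = tables["scenario_summary"].set_index(["scenario", "year"])
        density_gap = (
            t5["density_MgC_per_ha"] * t5["area_Mha"] - t5["stock_MtC"]
        ).abs().max()
        for scen, key in (("public_welfare", "pwf"), ("commercial", "com")):
            cum = float(t5.loc[(scen, 2060), "stock_MtC"] - t5.loc[(scen, 2018), "stock_MtC"])
            rows += [
                (f"cum_sink_total_{key}_scenario_MtC", cum,
                 stats[f"cum_sink_total_{key}_scenario_MtC"], 0.15),
                (f"avg_sink_total_{key}_scenario_MtC_per_a", cum / 42.0,
                 stats[f"avg_sink_total_{key}_scenario_MtC_per_a"], 0.1),
                (f"stock_2060_{key}_scenario_MtC",
                 stats["stock_existing_2060_MtC"] + stats[f"cum_sink_new_{key}_MtC"],
                 float(t5.loc[(scen, 2060), "stock_MtC"]), 0.15),
            ]
        rows += [
            ("scenario_density_area_consistency_MtC", float(density_gap), 0.0,
             0.05 * float(t5["area_Mha"].max())),
            ("best_scenario_cumulative_MtC",
             stats["cum_sink_total_pwf_scenario_MtC"] + stats["cum_mitigation_existing_improved_MtC"],
             stats["cum_best_scenario_MtC"], 0.15),
            ("best_scenario_avg_MtC_per_a", stats["cum_best_scenario_MtC"] / 42.0,
             stats["avg_best_scenario_MtC_per_a"], 0.1),
        ]
    return rows


_TABLE_FILES = (
    "inventory_2018",
    "cumulative_sinks_2019_2060",
    "scenario_summary",
    "reported_statistics",
)


def verify_identities(fixture_dir: str | Path | None = None) -> pd.DataFrame:
    """Recompute the published tables' internal arithmetic.

    Every check is an identity the published national accounting implies
    among its own printed numbers: column sums, class splits, stock
    differences versus cumulative sinks, cumulative/average consistency,
    the afforestation schedule, growth rates and percentage gains.
    Tolerances reflect printed one-decimal rounding (0.05 per rounded
    summand).

    With ``fixture_dir`` given, only tables present in that directory are
    checked (an empty directory yields an empty report); by default the
    packaged tables are used. Failures are reported in the ``passed``
    column, never raised.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name in _TABLE_FILES:
        if fixture_dir is None:
            path = packaged_data_path(f"{name}.csv")
        else:
            path = Path(fixture_dir) / f"{name}.csv"
            if not path.exists():
                continue
        tables[name] = pd.read_csv(path, comment="#")

    rows = _identity_rows(tables)
    report = pd.DataFrame(rows, columns=["identity", "computed", "reported", "tol"])
    if not report.empty:
        report["passed"] = (report["computed"] - report["reported"]).abs() <= report["tol"]
    else:
        report["passed"] = pd.Series(dtype=bool)
    return report
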