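"""National scenario assembly: existing forests plus new afforestation.

The national simulation combines (a) the 19 dominant species of the 2018
inventory, each split into a public-welfare and a commercial block with a
five-bin age-class structure, and (b) a national afforestation schedule
derived from forest-coverage targets: coverage rises to 26% of the land
area by 2035 and to the world-average 30.7% by 2050, the added area being
spread equally within each planning window (about 1.7 Mha/yr over
2019-2035 and 3.0 Mha/yr over 2036-2050, all of it arbor forest). Annual
planted area is allocated to species in proportion to their share of the
2018 arbor area. Two scenarios differ only in the use class assigned to
every newly planted stand: public welfare (never harvested) or commercial
(managed on each species' rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .growth import Cohort, GrowthParams, HarvestFlow, ManagementRegime, spin_up, step_cohort
from .parameters import ORGANS, SpeciesRecord

__all__ = [
    "AfforestationPlan",
    "ScenarioSpec",
    "NationalScenario",
    "build_afforestation_schedule",
    "allocate_by_species",
    "assemble_scenario",
    "simulate",
    "PLANTING_END",
]

#: Afforestation stops after the 2050 coverage target is met.
PLANTING_END = 2050

#: Arbor-forest area not covered by the 19 dominant species, Mha
#: (179.9 total arbor minus 161.8 dominant-species area in 2018).
DEFAULT_EXTRA_ARBOR_AREA = 18.1


def _round1(x: float) -> float:
    """Round half away from zero to one decimal, as national totals print."""
    import math

    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclass(frozen=True)
class AfforestationPlan:
    """Annual planted arbor area and its allocation across species.

    ``planted`` maps year -> Mha (zero after 2050); ``species_weights``
    maps species -> proportion of each year's area, summing to 1.
    """

    planted: Mapping[int, float]
    species_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for year, area in self.planted.items():
            if area < 0:
                raise ValueError(f"planted area in {year} negative: {area}")
            if year > PLANTING_END and area > 0:
                raise ValueError(f"planting in {year} is after the {PLANTING_END} horizon")
        if self.species_weights:
            total = sum(self.species_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"species weights sum to {total}, expected 1")

    def cumulative_by(self, year: int) -> float:
        """Total area planted in years <= ``year``, Mha."""
        return sum(a for y, a in self.planted.items() if y <= year)


@dataclass(frozen=True)
class ScenarioSpec:
    """Forest-use scenario: the class given to all new plantations."""

    new_forest_class: str = "public_welfare"
    horizon: tuple[int, int] = (2018, 2060)
    include_bioenergy: bool = True
    stove: str = "traditional"

    def __post_init__(self) -> None:
        if self.new_forest_class not in ("public_welfare", "commercial"):
            raise ValueError(f"unknown forest class {self.new_forest_class!r}")
        if self.stove not in ("traditional", "improved"):
            raise ValueError(f"unknown stove technology {self.stove!r}")
        if self.horizon[0] >= self.horizon[1]:
            raise ValueError(f"degenerate horizon {self.horizon}")


def build_afforestation_schedule(
    existing_forest_area: float = 220.5,
    coverage_now: float = 0.2296,
    coverage_2035: float = 0.26,
    coverage_2050: float = 0.307,
    land_area: float = 960.1,
    species_weights: Mapping[str, float] | None = None,
) -> AfforestationPlan:
    """Translate forest-coverage targets into an annual planting schedule.

    Target forest areas are coverage x land area, rounded to the 0.1 Mha
    the national plan prints (with the default land area this yields 249.6
    Mha for 2035 and 294.8 Mha for 2050). The area added within each
    window is spread equally across its years: 2019-2035 (17 years) and
    2036-2050 (15 years). All new plantation is arbor forest.
    """
    if land_area <= 0:
        raise ValueError(f"land area must be positive, got {land_area}")
    if not (coverage_now <= coverage_2035 <= coverage_2050):
        raise ValueError(
            f"coverage targets must be non-decreasing, got "
            f"{coverage_now}, {coverage_2035}, {coverage_2050}"
        )
    area_2035 = _round1(coverage_2035 * land_area)
    area_2050 = _round1(coverage_2050 * land_area)
    rate_1 = max(0.0, area_2035 - existing_forest_area) / 17.0
    rate_2 = max(0.0, area_2050 - area_2035) / 15.0
    planted = {year: rate_1 for year in range(2019, 2036)}
    planted.update({year: rate_2 for year in range(2036, 2051)})
    return AfforestationPlan(planted=planted, species_weights=dict(species_weights or {}))


def allocate_by_species(
    annual_area: float, species_areas_2018: Mapping[str, float]
) -> dict[str, float]:
    """Split one year's planted area across species by 2018 area shares.

    Allocations sum to ``annual_area`` exactly (the split is a plain
    proportional division, no rounding is applied).
    """
    total = sum(species_areas_2018.values())
    if total <= 0:
        raise ValueError("species areas are all zero")
    if any(a < 0 for a in species_areas_2018.values()):
        raise ValueError("negative species area")
    return {name: annual_area * a / total for name, a in species_areas_2018.items()}


@dataclass
class NationalScenario:
    """The assembled national cohort collection ready to simulate.

    ``cohorts`` holds (cohort, params, regime, plant_year) tuples;
    existing forests carry ``plant_year=None``. ``extra_area`` is arbor
    area outside the modelled species, carried so national area
    bookkeeping matches the full arbor-forest total.
    """

    spec: ScenarioSpec
    plan: AfforestationPlan
    cohorts: list[tuple[Cohort, GrowthParams, ManagementRegime, int | None]]
    extra_area: float = DEFAULT_EXTRA_ARBOR_AREA

    def total_area(self, year: int) -> float:
        """All-arbor area in a year: cohorts + unmodelled remainder, Mha."""
        existing = sum(c.area for c, _, _, py in self.cohorts if py is None)
        planted = self.plan.cumulative_by(year)
        return existing + self.extra_area + planted


def assemble_scenario(
    spec: ScenarioSpec,
    plan: AfforestationPlan,
    species_records: Sequence[SpeciesRecord],
    growth_params: Mapping[str, GrowthParams],
    regimes: Mapping[str, ManagementRegime],
    age_structures: Mapping[str, Mapping[int, float]],
    extra_area: float = DEFAULT_EXTRA_ARBOR_AREA,
) -> NationalScenario:
    """Build the national cohort collection for one scenario.

    Existing forests contribute one cohort per species, class and age bin
    (age shares apply equally to both classes; commercial bin ages are
    reduced modulo the species rotation so they are consistent with the
    logging cycle). New cohorts are added at age 0 in their plant year
    with the class the scenario assigns, public-welfare plantations
    carrying the unmanaged regime.

    ``age_structures`` maps species -> {2018 age: share of species area}.
    """
    missing = [r.name for r in species_records if r.name not in growth_params]
    if missing:
        raise ValueError(f"no growth parameters for species: {missing}")
    missing = [r.name for r in species_records if r.name not in age_structures]
    if missing:
        raise ValueError(f"no age structure for species: {missing}")

    unmanaged = ManagementRegime.unmanaged()
    cohorts: list[tuple[Cohort, GrowthParams, ManagementRegime, int | None]] = []
    for rec in species_records:
        p = growth_params[rec.name]
        regime = regimes.get(rec.name, unmanaged)
        structure = age_structures[rec.name]
        for forest_class, class_area, class_regime in (
            ("public_welfare", rec.area_pwf, unmanaged),
            ("commercial", rec.area_com, regime),
        ):
            if class_area <= 0:
                continue
            for age, share in structure.items():
                if share <= 0:
                    continue
                start_age = age
                if class_regime.rotation_years is not None:
                    start_age = age % class_regime.rotation_years
                cohort = spin_up(
                    rec.name, forest_class, class_area * share, start_age, p, class_regime
                )
                cohorts.append((cohort, p, class_regime, None))

    new_regimes = {
        name: (regimes.get(name, unmanaged) if spec.new_forest_class == "commercial" else unmanaged)
        for name in growth_params
    }
    areas_2018 = {r.name: r.total_area for r in species_records}
    for year, annual_area in sorted(plan.planted.items()):
        if annual_area <= 0:
            continue
        for name, area in allocate_by_species(annual_area, areas_2018).items():
            cohort = Cohort(name, spec.new_forest_class, area, 0, {o: 0.0 for o in ORGANS})
            cohorts.append((cohort, growth_params[name], new_regimes[name], year))

    return NationalScenario(spec=spec, plan=plan, cohorts=cohorts, extra_area=extra_area)


def simulate(scenario: NationalScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the national simulation over the scenario horizon.

    Returns
    -------
    stocks : DataFrame
        Tidy year-end states per (species, forest_class, year, origin):
        area A (Mha), density D (MgC/ha), stock C (MtC). ``origin`` is
        "existing" or "new". Stands not yet planted do not appear.
    harvests : DataFrame
        Per (species, year, origin) harvest flows: stemwood_carbon and
        residue_carbon, MtC. Public-welfare cohorts contribute nothing.
    """
    y0, y1 = scenario.spec.horizon
    state: list[tuple[Cohort, GrowthParams, ManagementRegime, int | None]] = []
    pending = sorted(
        ((py, c, p, r) for c, p, r, py in scenario.cohorts if py is not None),
        key=lambda item: item[0],
    )
    state = [(c, p, r, None) for c, p, r, py in scenario.cohorts if py is None]

    stock_rows: list[tuple] = []
    harvest_rows: list[tuple] = []

    def record(year: int) -> None:
        agg: dict[tuple[str, str, str], tuple[float, float]] = {}
        for c, _, _, py in state:
            origin = "existing" if py is None else "new"
            key = (c.species, c.forest_class, origin)
            area, stock = agg.get(key, (0.0, 0.0))
            agg[key] = (area + c.area, stock + c.stock)
        for (species, fc, origin), (area, stock) in agg.items():
            stock_rows.append((species, fc, origin, year, area, stock / area, stock))

    record(y0)
    pend_idx = 0
    for year in range(y0 + 1, y1 + 1):
        while pend_idx < len(pending) and pending[pend_idx][0] == year:
            py, c, p, r = pending[pend_idx]
            state.append((c, p, r, py))
            pend_idx += 1
        next_state = []
        for c, p, r, py in state:
            c2, flow = step_cohort(c, p, r, year)
            if flow.total > 0:
                origin = "existing" if py is None else "new"
                harvest_rows.append(
                    (c.species, origin, year, flow.stemwood_carbon, flow.residue_carbon)
                )
            next_state.append((c2, p, r, py))
        state = next_state
        record(year)

    stocks = pd.DataFrame(
        stock_rows, columns=["species", "forest_class", "origin", "year", "A", "D", "C"]
    ).sort_values(["species", "forest_class", "origin", "year"], ignore_index=True)
    harvests = (
        pd.DataFrame(
            harvest_rows,
            columns=["species", "origin", "year", "stemwood_carbon", "residue_carbon"],
        )
        .groupby(["species", "origin", "year"], as_index=False)
        .sum()
    )
    return stocks, harvests
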