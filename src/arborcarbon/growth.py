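"""Annual cohort simulator for even-aged forest stands.

A cohort is a patch of even-aged forest of one species and one use class
(public welfare or commercial) carrying four per-organ carbon pools in
MgC/ha. Stem growth follows a Chapman-Richards volume curve

    V(a) = v_max * (1 - exp(-k * a)) ** m        [m3/ha]

which is the standard monotone, asymptotic functional form of empirical
stand growth modelling. Each simulated year:

1. the stem pool gains ``wood_density * carbon_fraction[stem] * dV`` where
   dV is the annual volume increment;
2. root/foliage/branch pools gain in proportion to their share of the
   biomass increment;
3. foliage, branch and root pools shed their annual turnover fraction;
4. stem mortality removes a fraction of every pool;
5. if the cohort reaches a thinning age the scheduled fraction of all
   pools is removed; at the rotation age everything is removed and the
   stand is replanted at age 0 the same year.

Turnover and mortality carbon leaves the vegetation accounting (litter and
soil pools are not tracked; all reported quantities are vegetation carbon).
Harvested carbon is split into stemwood routed to products and residue
available as bioenergy feedstock. Public-welfare cohorts carry no
management regime and never produce harvest flows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .parameters import ORGANS

__all__ = [
    "GrowthParams",
    "ManagementRegime",
    "Cohort",
    "HarvestFlow",
    "StepFluxes",
    "stem_volume",
    "step_cohort",
    "step_cohort_with_fluxes",
    "spin_up",
    "density_trajectory",
    "fit_growth_curve",
]

_SOFT_ORGANS = ("root", "foliage", "branch")


@dataclass(frozen=True)
class GrowthParams:
    """Species growth parameters of the cohort simulator.

    Parameters
    ----------
    v_max
        Asymptotic stem volume, m3/ha.
    k
        Growth rate of the Chapman-Richards curve, 1/yr.
    m
        Shape exponent (dimensionless); larger values delay the inflection.
    wood_density
        Stem dry matter per unit volume, Mg/m3.
    organ_share
        Organ -> share of the annual biomass increment; shares sum to 1.
    turnover
        Organ -> annual fraction shed, for root/foliage/branch.
    mortality
        Annual stem mortality as a fraction of every pool, [0, 1).
    carbon_fraction
        Organ -> carbon content of dry matter; defaults to the 0.5
        convention, overridden per species from the organ-content table.
    """

    v_max: float
    k: float
    m: float
    wood_density: float
    organ_share: Mapping[str, float]
    turnover: Mapping[str, float]
    mortality: float
    carbon_fraction: Mapping[str, float] = field(
        default_factory=lambda: {o: 0.5 for o in ORGANS}
    )

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k <= 0:
            raise ValueError(f"v_max and k must be positive (v_max={self.v_max}, k={self.k})")
        share_sum = sum(self.organ_share.values())
        if abs(share_sum - 1.0) > 1e-9:
            raise ValueError(f"organ shares sum to {share_sum}, expected 1")
        if self.organ_share.get("stem", 0.0) <= 0:
            raise ValueError("stem must carry a positive share of the biomass increment")
        for organ, rate in self.turnover.items():
            if not (0 <= rate < 1):
                raise ValueError(f"turnover[{organ}]={rate} outside [0, 1)")
        if not (0 <= self.mortality < 1):
            raise ValueError(f"mortality={self.mortality} outside [0, 1)")


@dataclass(frozen=True)
class ManagementRegime:
    """Thinning and final-felling schedule of a commercial stand.

    ``rotation_years=None`` (the public-welfare regime) disables all
    removals. ``residue_fraction`` is the share of each harvest routed to
    bioenergy feedstock; the remainder is stemwood leaving for products.
    """

    rotation_years: int | None = None
    thinnings: tuple[tuple[int, float], ...] = ()
    residue_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not (0 <= self.residue_fraction <= 1):
            raise ValueError(f"residue_fraction={self.residue_fraction} outside [0, 1]")
        for age, frac in self.thinnings:
            if not (0 < frac <= 1):
                raise ValueError(f"thinning fraction {frac} at age {age} outside (0, 1]")
            if self.rotation_years is not None and age >= self.rotation_years:
                raise ValueError(f"thinning age {age} >= rotation {self.rotation_years}")

    @classmethod
    def unmanaged(cls) -> "ManagementRegime":
        """The public-welfare regime: no thinning, no felling."""
        return cls(rotation_years=None, thinnings=())

    @property
    def is_managed(self) -> bool:
        return self.rotation_years is not None or bool(self.thinnings)

    def removal_at(self, age: int) -> float:
        """Fraction of all pools removed when the cohort reaches ``age``."""
        if self.rotation_years is not None and age >= self.rotation_years:
            return 1.0
        for t_age, frac in self.thinnings:
            if age == t_age:
                return frac
        return 0.0


@dataclass(frozen=True)
class Cohort:
    """An even-aged stand patch: per-organ carbon pools on a fixed area."""

    species: str
    forest_class: str  # "public_welfare" | "commercial"
    area: float  # Mha
    age: int  # yr
    pools: Mapping[str, float]  # organ -> MgC/ha

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        for organ, pool in self.pools.items():
            if pool < 0:
                raise ValueError(f"pool {organ}={pool} negative")

    @property
    def density(self) -> float:
        """Total vegetation carbon density, MgC/ha."""
        return sum(self.pools.values())

    @property
    def stock(self) -> float:
        """Vegetation carbon stock on the patch, MtC (MgC/ha x Mha)."""
        return self.density * self.area


@dataclass(frozen=True)
class HarvestFlow:
    """Carbon removed by management in one year, MtC.

    ``stemwood_carbon`` leaves for wood products; ``residue_carbon`` is the
    logging/processing residue available as bioenergy feedstock.
    """

    stemwood_carbon: float = 0.0
    residue_carbon: float = 0.0
    year: int | None = None
    species: str | None = None

    @property
    def total(self) -> float:
        return self.stemwood_carbon + self.residue_carbon


@dataclass(frozen=True)
class StepFluxes:
    """Carbon flux bookkeeping of one cohort step, MtC at patch scale."""

    increment: float
    turnover: float
    mortality: float
    harvest: float


def stem_volume(age: float, p: GrowthParams) -> float:
    """Chapman-Richards stem volume at a stand age, m3/ha.

    Zero at age 0, monotone non-decreasing, asymptotic to ``p.v_max``.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    return p.v_max * (1.0 - math.exp(-p.k * age)) ** p.m


def step_cohort_with_fluxes(
    c: Cohort, p: GrowthParams, r: ManagementRegime, year: int | None = None
) -> tuple[Cohort, HarvestFlow, StepFluxes]:
    """Advance a cohort one year and account every carbon flux.

    Returns the aged cohort, the harvest flow (zero unless a thinning or
    the final felling fell in this step) and the flux breakdown satisfying
    the per-step balance  d(pools)*area = increment - turnover - mortality
    - harvest  exactly (to float round-off).
    """
    new_age = c.age + 1
    dv = stem_volume(new_age, p) - stem_volume(c.age, p)
    cf = p.carbon_fraction
    share_stem = p.organ_share["stem"]
    biomass_inc = p.wood_density * dv / share_stem  # total dry-matter increment, Mg/ha

    pools = dict(c.pools)
    inc_total = 0.0
    for organ in ORGANS:
        inc = biomass_inc * p.organ_share.get(organ, 0.0) * cf[organ]
        pools[organ] = pools.get(organ, 0.0) + inc
        inc_total += inc

    turn_total = 0.0
    for organ in _SOFT_ORGANS:
        shed = pools[organ] * p.turnover.get(organ, 0.0)
        pools[organ] -= shed
        turn_total += shed

    mort_total = 0.0
    for organ in ORGANS:
        dead = pools[organ] * p.mortality
        pools[organ] -= dead
        mort_total += dead

    removal = r.removal_at(new_age)
    harvest_density = 0.0
    if removal > 0.0:
        for organ in ORGANS:
            taken = pools[organ] * removal
            pools[organ] -= taken
            harvest_density += taken
        if removal >= 1.0:
            new_age = 0  # clear-fell: replant the same year

    harvest = harvest_density * c.area
    flow = HarvestFlow(
        stemwood_carbon=harvest * (1.0 - r.residue_fraction),
        residue_carbon=harvest * r.residue_fraction,
        year=year,
        species=c.species,
    )
    fluxes = StepFluxes(
        increment=inc_total * c.area,
        turnover=turn_total * c.area,
        mortality=mort_total * c.area,
        harvest=harvest,
    )
    return replace(c, age=new_age, pools=pools), flow, fluxes


def step_cohort(
    c: Cohort, p: GrowthParams, r: ManagementRegime, year: int | None = None
) -> tuple[Cohort, HarvestFlow]:
    """Advance a cohort one year; see :func:`step_cohort_with_fluxes`."""
    cohort, flow, _ = step_cohort_with_fluxes(c, p, r, year)
    return cohort, flow


def spin_up(
    species: str,
    forest_class: str,
    area: float,
    age: int,
    p: GrowthParams,
    r: ManagementRegime,
) -> Cohort:
    """Grow a cohort from bare ground to a given stand age.

    Used to reconstruct the state of forests already standing at the start
    of the simulation horizon. The management regime applies during the
    spin-up, so thinned stands start with thinned pools. The requested age
    must lie below the rotation (initial ages of commercial stands are
    reduced modulo the rotation before calling).
    """
    if r.rotation_years is not None and age >= r.rotation_years:
        raise ValueError(f"spin-up age {age} >= rotation {r.rotation_years}")
    c = Cohort(species, forest_class, area, 0, {o: 0.0 for o in ORGANS})
    for _ in range(age):
        c, _ = step_cohort(c, p, r)
    return c


def density_trajectory(
    species: str,
    p: GrowthParams,
    r: ManagementRegime,
    age_structure: Mapping[int, float],
    years: Sequence[int] = range(2018, 2061),
) -> "pd.Series":
    """Area-weighted carbon-density series of one species, MgC/ha.

    ``age_structure`` maps 2018 stand age -> area (Mha). Stocks are
    year-end states: the first value is the spun-up state in ``years[0]``
    and each later value follows one annual step of every cohort.
    """
    import pandas as pd

    ages = {a: (a % r.rotation_years if r.rotation_years else a) for a in age_structure}
    if not age_structure:
        raise ValueError("age structure is empty")
    total_area = sum(age_structure.values())
    if total_area <= 0:
        raise ValueError("age structure has zero total area")
    cohorts = [
        spin_up(species, "any", area, ages[a], p, r) for a, area in age_structure.items()
    ]
    out = {}
    years = list(years)
    out[years[0]] = sum(c.stock for c in cohorts) / total_area
    for year in years[1:]:
        cohorts = [step_cohort(c, p, r, year)[0] for c in cohorts]
        out[year] = sum(c.stock for c in cohorts) / total_area
    return pd.Series(out, name=species)


def fit_growth_curve(
    ages: Sequence[float], volumes: Sequence[float], m: float, p0: tuple[float, float] = (100.0, 0.05)
) -> tuple[float, float]:
    """Least-squares recovery of (v_max, k) from a stem-volume series.

    The shape exponent ``m`` is held fixed (it is strongly collinear with
    k on short series); on a noiseless Chapman-Richards series the
    generating (v_max, k) are recovered to high precision.
    """
    ages = np.asarray(ages, dtype=float)
    volumes = np.asarray(volumes, dtype=float)

    def resid(theta):
        v_max, k = theta
        return v_max * (1.0 - np.exp(-k * ages)) ** m - volumes

    sol = least_squares(resid, x0=p0, bounds=([1e-9, 1e-9], [np.inf, np.inf]), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return float(sol.x[0]), float(sol.x[1])
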