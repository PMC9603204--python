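"""Synthetic growth parameters, age structures and province tables.

The national simulation needs inputs that the inventory does not print:
per-species growth-curve parameters, wood densities, turnover and
mortality rates, rotation/thinning schedules, the 2018 age-class
structure, and per-province volume tables for the climate-reference rule.
This module generates all of them as pure functions of a single integer
seed, with the statistical structure the analysis assumes:

* every species belongs to a growth archetype (fast broadleaf, broadleaf,
  mixed, fast conifer, slow conifer) that fixes realistic ranges for
  growth rate, wood density, turnover and rotation length (fast-growing
  plantation species carry short rotations, slow conifers long ones);
* 2018 carbon densities are *calibrated*: each species' asymptotic volume
  v_max is solved so that its simulated 2018 density (under its generated
  age structure and management) hits a target density, and the targets
  are scaled so the 19-species national 2018 stock matches the published
  6876.9 MtC while every species stays inside the published 2018 density
  range of 28.4-144.3 MgC/ha. Because every carbon pool is exactly
  linear in v_max, the calibration solves in closed form (one unit-v_max
  simulation per species) and is verified by re-simulation;
* the age structure uses five bins (young / middle / near-mature /
  mature / over-mature) at deterministic midpoint ages, with the national
  young+middle area share of 63.9%, overridable per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthParams, ManagementRegime, spin_up
from .parameters import ORGANS, ProvinceVolumeRecord, SpeciesRecord, load_species_table

__all__ = [
    "FixtureSpec",
    "ARCHETYPE_OF",
    "ARCHETYPES",
    "generate_growth_params",
    "generate_management",
    "generate_age_structure",
    "age_share_map",
    "generate_province_volume_table",
    "write_fixture_bundle",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when a species' density target cannot be met."""


#: Growth archetype of each dominant species.
ARCHETYPE_OF: Mapping[str, str] = {
    "Eucalyptus": "fast_broadleaf",
    "Poplar": "fast_broadleaf",
    "Soft broad-leaved forest": "fast_broadleaf",
    "Broad-leaved mixed forest": "broadleaf",
    "Quercus": "broadleaf",
    "Hardwood broad-leaved forest": "broadleaf",
    "Birch": "broadleaf",
    "Coniferous and broad-leaved mixed forest": "mixed",
    "Coniferous mixed forests": "mixed",
    "Chinese fir": "fast_conifer",
    "Masson pine": "fast_conifer",
    "Pinus yunnanensis": "fast_conifer",
    "Pinus kesiya": "fast_conifer",
    "Larch": "slow_conifer",
    "Fir": "slow_conifer",
    "Spruce": "slow_conifer",
    "Pinus densata": "slow_conifer",
    "Cypress": "slow_conifer",
    "Pinus tabulaeformis": "slow_conifer",
}

#: Per-archetype parameter ranges: growth rate k (1/yr), shape m, wood
#: density (Mg/m3), foliage turnover, rotation bounds (yr).
ARCHETYPES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "fast_broadleaf": {"k": (0.055, 0.09), "m": (1.8, 2.3), "wd": (0.38, 0.52), "tf": (0.25, 0.40), "rot": (8, 22)},
    "broadleaf": {"k": (0.022, 0.038), "m": (2.0, 2.6), "wd": (0.45, 0.58), "tf": (0.25, 0.40), "rot": (36, 50)},
    "mixed": {"k": (0.026, 0.045), "m": (2.0, 2.5), "wd": (0.40, 0.50), "tf": (0.18, 0.30), "rot": (31, 40)},
    "fast_conifer": {"k": (0.040, 0.065), "m": (1.8, 2.4), "wd": (0.35, 0.45), "tf": (0.10, 0.20), "rot": (23, 30)},
    "slow_conifer": {"k": (0.016, 0.028), "m": (2.0, 2.6), "wd": (0.35, 0.42), "tf": (0.08, 0.18), "rot": (50, 61)},
}

#: Age-bin labels and midpoint ages as fractions of the archetype's
#: upper rotation bound (the maturity scale).
AGE_BINS: tuple[tuple[str, float], ...] = (
    ("young", 0.15),
    ("middle", 0.40),
    ("near_mature", 0.70),
    ("mature", 1.00),
    ("over_mature", 1.35),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generators need, all driven by one seed.

    ``young_middle_share`` is the national share of young plus
    middle-aged area (63.9% in the 2018 inventory); ``ym_overrides``
    raises or lowers it for individual species (the inventory notes
    shares near 80% for eucalyptus, cypress and hardwood broad-leaved
    forest). ``national_stock_2018`` is the calibration target for the
    19-species 2018 stock, MtC.
    """

    seed: int = 0
    density_range_2018: tuple[float, float] = (28.4, 144.3)
    density_range_2060: tuple[float, float] = (44.6, 212.2)
    young_middle_share: float = 0.639
    ym_overrides: Mapping[str, float] = field(default_factory=dict)
    rotation_bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {g: spec["rot"] for g, spec in ARCHETYPES.items()}
    )
    national_stock_2018: float = 6876.9
    residue_fraction: float = 0.4
    calibration_margin: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (self.density_range_2018, self.density_range_2060):
            if lo >= hi:
                raise ValueError(f"density range ({lo}, {hi}) not ordered")
        if not (0 <= self.young_middle_share <= 1):
            raise ValueError(f"young_middle_share={self.young_middle_share} outside [0, 1]")
        for name, share in self.ym_overrides.items():
            if not (0 <= share <= 1):
                raise ValueError(f"ym override for {name}={share} outside [0, 1]")


def _rng(spec_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([spec_seed, stream, index])


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def generate_management(
    spec: FixtureSpec, species: Sequence[str] | None = None
) -> dict[str, ManagementRegime]:
    """Commercial-forest rotation and thinning schedules per species.

    One thinning removing 15% of standing pools at 40% of the rotation
    (dropped for very short rotations where the thinning age would not
    fit). Deterministic given the seed.
    """
    if species is None:
        species = list(ARCHETYPE_OF)
    out = {}
    for i, name in enumerate(species):
        group = ARCHETYPE_OF[name]
        lo, hi = spec.rotation_bounds[group]
        rng = _rng(spec.seed, 1, i)
        rotation = int(rng.integers(lo, hi + 1))
        thin_age = int(round(0.4 * rotation))
        thinnings = ((thin_age, 0.15),) if 1 < thin_age < rotation else ()
        out[name] = ManagementRegime(
            rotation_years=rotation, thinnings=thinnings, residue_fraction=spec.residue_fraction
        )
    return out


def generate_age_structure(spec: FixtureSpec, species: SpeciesRecord) -> pd.DataFrame:
    """Five age-class bins for one species' 2018 area.

    Returns a frame with columns ``bin``, ``age`` (2018 stand age, yr),
    ``share`` and ``area`` (Mha, summing to the species total). The
    young+middle share follows the spec (national default or a
    per-species override); shares within each maturity block are fixed
    proportions, so the structure is fully deterministic.
    """
    group = ARCHETYPE_OF[species.name]
    maturity = spec.rotation_bounds[group][1]
    ym = spec.ym_overrides.get(species.name, spec.young_middle_share)
    shares = np.array([0.55 * ym, 0.45 * ym, 0.40 * (1 - ym), 0.35 * (1 - ym), 0.25 * (1 - ym)])
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError(f"bin shares sum to {shares.sum()}")
    rows = []
    for (label, age_frac), share in zip(AGE_BINS, shares):
        age = max(1, int(round(age_frac * maturity)))
        rows.append((label, age, float(share), float(share) * species.total_area))
    return pd.DataFrame(rows, columns=["bin", "age", "share", "area"])


def age_share_map(structure: pd.DataFrame) -> dict[int, float]:
    """Collapse an age-structure frame to {age: share} for assembly."""
    out: dict[int, float] = {}
    for _, row in structure.iterrows():
        out[int(row["age"])] = out.get(int(row["age"]), 0.0) + float(row["share"])
    return out


def _density_targets(
    spec: FixtureSpec, records: Sequence[SpeciesRecord], wood_density: Mapping[str, float]
) -> dict[str, float]:
    """Per-species 2018 density targets, MgC/ha.

    Seeded from each species' unit-area stock volume (dense mature stands
    like fir sit high, sparse plantations like eucalyptus sit low), then
    iteratively rescaled and clipped so the area-weighted national stock
    matches the calibration target with every species strictly inside the
    published 2018 density range.
    """
    lo, hi = spec.density_range_2018
    lo += spec.calibration_margin
    hi -= spec.calibration_margin
    areas = np.array([r.total_area for r in records])
    # biomass expansion ~1.9 over stem, carbon fraction ~0.47
    d = np.array(
        [
            np.clip(r.volume_2018 / r.total_area * wood_density[r.name] * 1.9 * 0.47, lo, hi)
            for r in records
        ]
    )
    target = spec.national_stock_2018
    for _ in range(200):
        stock = float(d @ areas)
        if abs(stock - target) / target < 1e-12:
            break
        # rescale only where clipping still leaves room
        free = (d > lo) | (target > stock)
        free &= (d < hi) | (target < stock)
        adjustable = float(d[free] @ areas[free])
        if adjustable <= 0:
            raise CalibrationError("density targets fully clipped; cannot reach national stock")
        d[free] = np.clip(d[free] * (1 + (target - stock) / adjustable), lo, hi)
    else:
        raise CalibrationError(f"national-stock calibration did not converge (at {stock:.1f} MtC)")
    return {r.name: float(di) for r, di in zip(records, d)}


def _density_2018(
    rec: SpeciesRecord,
    p: GrowthParams,
    regime: ManagementRegime,
    structure: Mapping[int, float],
) -> float:
    """Area-weighted 2018 density of a species over both use classes."""
    total, weight = 0.0, 0.0
    for forest_class, area, r in (
        ("public_welfare", rec.area_pwf, ManagementRegime.unmanaged()),
        ("commercial", rec.area_com, regime),
    ):
        if area <= 0:
            continue
        for age, share in structure.items():
            a = age % r.rotation_years if r.rotation_years else age
            c = spin_up(rec.name, forest_class, area * share, a, p, r)
            total += c.stock
            weight += c.area
    return total / weight


def generate_growth_params(
    spec: FixtureSpec,
    species_records: Sequence[SpeciesRecord] | None = None,
    management: Mapping[str, ManagementRegime] | None = None,
) -> dict[str, GrowthParams]:
    """Growth parameters for every species, calibrated to 2018 densities.

    Archetype ranges drive the draws of k, m, wood density, organ shares,
    turnover and mortality; v_max is then solved so the species' 2018
    density (under its generated age structure and management) equals its
    calibrated target. Deterministic given ``spec.seed``.

    Raises
    ------
    CalibrationError
        If a species' verified density misses its target, naming the
        species.
    """
    if species_records is None:
        species_records = load_species_table()
    if management is None:
        management = generate_management(spec, [r.name for r in species_records])

    draws: dict[str, GrowthParams] = {}
    for i, rec in enumerate(species_records):
        group = ARCHETYPE_OF[rec.name]
        arch = ARCHETYPES[group]
        rng = _rng(spec.seed, 2, i)
        shares = np.array(
            [
                rng.uniform(0.58, 0.66),  # stem
                rng.uniform(0.17, 0.23),  # root
                rng.uniform(0.04, 0.08),  # foliage
                rng.uniform(0.09, 0.14),  # branch
            ]
        )
        shares /= shares.sum()
        draws[rec.name] = GrowthParams(
            v_max=1.0,  # placeholder, calibrated below
            k=_uniform(rng, arch["k"]),
            m=_uniform(rng, arch["m"]),
            wood_density=_uniform(rng, arch["wd"]),
            organ_share=dict(zip(ORGANS, map(float, shares))),
            turnover={
                "foliage": _uniform(rng, arch["tf"]),
                "branch": _uniform(rng, (0.02, 0.04)),
                "root": _uniform(rng, (0.02, 0.06)),
            },
            mortality=_uniform(rng, (0.002, 0.007)),
            carbon_fraction=dict(rec.carbon_fraction),
        )

    wood_density = {name: p.wood_density for name, p in draws.items()}
    targets = _density_targets(spec, species_records, wood_density)

    out: dict[str, GrowthParams] = {}
    for rec in species_records:
        structure = age_share_map(generate_age_structure(spec, rec))
        regime = management[rec.name]
        unit = _density_2018(rec, draws[rec.name], regime, structure)
        if unit <= 0:
            raise CalibrationError(f"{rec.name}: zero density at unit asymptotic volume")
        # pools are exactly linear in v_max, so the target solves directly
        p = replace(draws[rec.name], v_max=targets[rec.name] / unit)
        achieved = _density_2018(rec, p, regime, structure)
        if abs(achieved - targets[rec.name]) > 1e-6 * max(1.0, targets[rec.name]):
            raise CalibrationError(
                f"{rec.name}: calibration missed target "
                f"({achieved:.4f} vs {targets[rec.name]:.4f} MgC/ha)"
            )
        out[rec.name] = p
    return out


def generate_province_volume_table(
    seed: int, n_provinces: int, national_unit_volume: float = 100.0
) -> list[ProvinceVolumeRecord]:
    """Synthetic per-province volume/area table for the climate rule.

    Unit-area volumes spread log-normally (sd 0.3) around the national
    level; areas are uniform on 0.1-5 Mha. Deterministic given the seed.
    """
    if n_provinces < 1:
        raise ValueError(f"need at least one province, got {n_provinces}")
    rng = np.random.default_rng([seed, 3])
    out = []
    for i in range(n_provinces):
        area = float(rng.uniform(0.1, 5.0))
        uav = national_unit_volume * float(np.exp(rng.normal(0.0, 0.3)))
        out.append(ProvinceVolumeRecord(province=f"P{i:02d}", volume=uav * area, area=area))
    return out


def write_fixture_bundle(out_dir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Write the full synthetic parameter bundle as CSVs.

    Produces growth, management, age-structure and province tables.
    Byte-identical on regeneration with the same spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = load_species_table()
    management = generate_management(spec, [r.name for r in records])
    params = generate_growth_params(spec, records, management)

    growth_rows = []
    for name, p in params.items():
        row = {
            "species": name,
            "v_max_m3_per_ha": p.v_max,
            "k_per_yr": p.k,
            "m": p.m,
            "wood_density_Mg_per_m3": p.wood_density,
            "mortality": p.mortality,
        }
        row.update({f"share_{o}": p.organ_share[o] for o in ORGANS})
        row.update({f"turnover_{o}": p.turnover[o] for o in ("foliage", "branch", "root")})
        row.update({f"cf_{o}": p.carbon_fraction[o] for o in ORGANS})
        growth_rows.append(row)

    mgmt_rows = []
    for name, r in management.items():
        thin_age, thin_frac = (r.thinnings[0] if r.thinnings else (np.nan, np.nan))
        mgmt_rows.append(
            {
                "species": name,
                "rotation_years": r.rotation_years,
                "thinning_age": thin_age,
                "thinning_fraction": thin_frac,
                "residue_fraction": r.residue_fraction,
            }
        )

    age_frames = []
    for rec in records:
        frame = generate_age_structure(spec, rec)
        frame.insert(0, "species", rec.name)
        age_frames.append(frame)

    provinces = generate_province_volume_table(spec.seed, 10)

    paths = {
        "growth": out_dir / "growth_params.csv",
        "management": out_dir / "management.csv",
        "age_structure": out_dir / "age_structure.csv",
        "provinces": out_dir / "provinces.csv",
    }
    pd.DataFrame(growth_rows).to_csv(paths["growth"], index=False)
    pd.DataFrame(mgmt_rows).to_csv(paths["management"], index=False)
    pd.concat(age_frames, ignore_index=True).to_csv(paths["age_structure"], index=False)
    pd.DataFrame([vars(p) for p in provinces]).to_csv(paths["provinces"], index=False)
    return paths
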