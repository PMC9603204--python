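"""Typed readers and validators for the national inventory parameter tables.

The package works in a fixed unit system throughout: areas in Mha, stock
volumes in Mm3, carbon densities in MgC/ha, carbon stocks and sinks in MtC
(1 MgC/ha x 1 Mha = 1 MtC, so stock = density x area is a bare product),
and greenhouse-gas emission factors in g of gas per kg of fuel burned.

Three delimited tables ship with the package:

* ``inventory_2018.csv`` -- stock volume and public-welfare/commercial area
  of the 19 dominant tree species of China's arbor forests (ninth national
  forest resources inventory, statistical year 2018);
* ``carbon_fractions.csv`` -- organ carbon contents (stem/root/foliage/
  branch, percent of dry mass), with species sharing one measurement
  grouped in a single row;
* ``emission_factors.csv`` -- per-gas emission factors for anthracite coal
  stoves and two biomass stove technologies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ORGANS",
    "GASES",
    "SpeciesRecord",
    "EmissionFactorSet",
    "FuelSpec",
    "ProvinceVolumeRecord",
    "ParameterError",
    "load_species_table",
    "load_emission_factors",
    "load_reported_statistics",
    "write_species_table",
    "unit_area_volume",
    "select_reference_province",
    "packaged_data_path",
]

#: Tree organs with distinct carbon pools, in canonical order.
ORGANS: tuple[str, ...] = ("stem", "root", "foliage", "branch")

#: Greenhouse gases tracked by the substitution calculus, in canonical order.
GASES: tuple[str, ...] = ("CO2", "CH4", "N2O", "CO", "TNMOC")

# Organ carbon contents observed across Chinese tree species fall in a
# narrow band; fractions outside it indicate a units or parsing mistake.
_CF_LO, _CF_HI = 0.40, 0.52


class ParameterError(ValueError):
    """Raised when a parameter table fails validation."""


def packaged_data_path(name: str) -> Path:
    """Return the filesystem path of a CSV shipped in ``arborcarbon.data``."""
    return Path(str(resources.files("arborcarbon.data").joinpath(name)))


@dataclass(frozen=True)
class SpeciesRecord:
    """One inventory row: a dominant tree species and its 2018 state.

    Parameters
    ----------
    name
        Species (or species-group) label as it appears in the inventory.
    volume_2018
        National stock volume in 2018, Mm3.
    area_pwf, area_com
        Public-welfare and commercial forest area, Mha.
    carbon_fraction
        Organ -> carbon content as a proportion of dry mass (0-1), for
        all four organs in :data:`ORGANS`.
    """

    name: str
    volume_2018: float
    area_pwf: float
    area_com: float
    carbon_fraction: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume_2018 < 0:
            raise ParameterError(f"{self.name}: negative volume {self.volume_2018}")
        if self.area_pwf < 0 or self.area_com < 0:
            raise ParameterError(
                f"{self.name}: negative area (pwf={self.area_pwf}, com={self.area_com})"
            )
        missing = set(ORGANS) - set(self.carbon_fraction)
        if missing:
            raise ParameterError(f"{self.name}: missing organ carbon fraction {sorted(missing)}")
        extra = set(self.carbon_fraction) - set(ORGANS)
        if extra:
            raise ParameterError(f"{self.name}: unknown organ {sorted(extra)}")
        for organ, cf in self.carbon_fraction.items():
            if not (_CF_LO < cf < _CF_HI):
                raise ParameterError(
                    f"{self.name}: carbon fraction of {organ} = {cf} outside ({_CF_LO}, {_CF_HI})"
                )

    @property
    def total_area(self) -> float:
        """Total species area, Mha."""
        return self.area_pwf + self.area_com


@dataclass(frozen=True)
class EmissionFactorSet:
    """Per-gas emission factors of one fuel burned in one device, g/kg."""

    fuel: str
    technology: str
    ef: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.ef) != set(GASES):
            raise ParameterError(
                f"{self.fuel}/{self.technology}: gas set {sorted(self.ef)} != {sorted(GASES)}"
            )
        for gas, value in self.ef.items():
            if value < 0:
                raise ParameterError(f"{self.fuel}/{self.technology}: negative factor {gas}={value}")


@dataclass(frozen=True)
class FuelSpec:
    """Energy content (MJ/kg) and device conversion efficiency of a fuel."""

    energy_content: float
    efficiency: float

    def __post_init__(self) -> None:
        if self.energy_content <= 0:
            raise ParameterError(f"energy_content must be positive, got {self.energy_content}")
        if not (0 < self.efficiency <= 1):
            raise ParameterError(f"efficiency must be in (0, 1], got {self.efficiency}")


@dataclass(frozen=True)
class ProvinceVolumeRecord:
    """Stock volume (Mm3) and forest area (Mha) of one species in a province."""

    province: str
    volume: float
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ParameterError(f"{self.province}: area must be positive, got {self.area}")


def _expand_fraction_groups(fractions: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Expand grouped carbon-fraction rows ("Spruce, Fir") to one per species."""
    out: dict[str, dict[str, float]] = {}
    cols = {"stem": "stem_pct", "root": "root_pct", "foliage": "foliage_pct", "branch": "branch_pct"}
    for _, row in fractions.iterrows():
        cf = {organ: float(row[col]) / 100.0 for organ, col in cols.items()}
        for name in str(row["species"]).split(","):
            out[name.strip()] = cf
    return out


def load_species_table(
    inventory: str | Path | io.IOBase | None = None,
    fractions: str | Path | io.IOBase | None = None,
) -> list[SpeciesRecord]:
    """Load and validate the species inventory joined to organ carbon contents.

    Both arguments default to the packaged national tables. Species whose
    carbon-content row is shared (grouped species field) receive identical
    carbon fractions.

    Raises
    ------
    ParameterError
        On a missing organ, negative area/volume, or a species without a
        carbon-content record; the message names the row and field.
    """
    if inventory is None:
        inventory = packaged_data_path("inventory_2018.csv")
    if fractions is None:
        fractions = packaged_data_path("carbon_fractions.csv")
    inv = pd.read_csv(inventory, comment="#")
    if inv.empty:
        return []
    frac = pd.read_csv(fractions, comment="#")
    cf_by_species = _expand_fraction_groups(frac)

    records = []
    for _, row in inv.iterrows():
        name = str(row["species"]).strip()
        if name not in cf_by_species:
            raise ParameterError(f"{name}: no carbon-fraction record for this species")
        records.append(
            SpeciesRecord(
                name=name,
                volume_2018=float(row["volume_Mm3"]),
                area_pwf=float(row["area_public_welfare_Mha"]),
                area_com=float(row["area_commercial_Mha"]),
                carbon_fraction=cf_by_species[name],
            )
        )
    return records


def write_species_table(records: Sequence[SpeciesRecord], inventory_path: str | Path) -> None:
    """Write an inventory CSV that :func:`load_species_table` reads back."""
    pd.DataFrame(
        {
            "species": [r.name for r in records],
            "volume_Mm3": [r.volume_2018 for r in records],
            "area_public_welfare_Mha": [r.area_pwf for r in records],
            "area_commercial_Mha": [r.area_com for r in records],
        }
    ).to_csv(inventory_path, index=False)


def load_emission_factors(
    source: str | Path | io.IOBase | None = None,
) -> dict[tuple[str, str], EmissionFactorSet]:
    """Load the fuel/technology emission-factor registry.

    Returns a mapping keyed by ``(fuel, technology)``.
    """
    if source is None:
        source = packaged_data_path("emission_factors.csv")
    table = pd.read_csv(source, comment="#")
    out: dict[tuple[str, str], EmissionFactorSet] = {}
    for _, row in table.iterrows():
        efs = EmissionFactorSet(
            fuel=str(row["fuel"]).strip(),
            technology=str(row["technology"]).strip(),
            ef={gas: float(row[gas]) for gas in GASES},
        )
        out[(efs.fuel, efs.technology)] = efs
    return out


def load_reported_statistics(source: str | Path | None = None) -> dict[str, float]:
    """Load the published national headline statistics as name -> value."""
    if source is None:
        source = packaged_data_path("reported_statistics.csv")
    table = pd.read_csv(source, comment="#")
    return dict(zip(table["name"], table["value"].astype(float)))


def unit_area_volume(volume: float, area: float) -> float:
    """Stock volume per unit area, m3/ha (Mm3 / Mha = m3/ha exactly)."""
    if area <= 0:
        raise ParameterError(f"area must be positive, got {area}")
    return volume / area


def select_reference_province(
    national: ProvinceVolumeRecord, provinces: Iterable[ProvinceVolumeRecord]
) -> str:
    """Pick the province whose per-hectare stock volume is closest to national.

    This is the climate downscaling rule of the source inventory analysis:
    a species' national-scale growth is represented by the climate of the
    province whose unit-area volume best matches the national level. Exact
    ties resolve to the first province in input order.
    """
    provinces = list(provinces)
    if not provinces:
        raise ParameterError("province list is empty")
    target = unit_area_volume(national.volume, national.area)
    return min(
        provinces, key=lambda p: abs(unit_area_volume(p.volume, p.area) - target)
    ).province
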