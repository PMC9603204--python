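"""Stock/sink bookkeeping for vegetation carbon series.

The two accounting identities are

    C_t = D_t * A_t          (stock = density x area; MgC/ha x Mha = MtC)
    S_t = C_t - C_{t-1}      (the annual sink is the first difference)

applied per species and forest-use class and then aggregated. A stock
series is a tidy DataFrame with columns ``species``, ``forest_class``,
``year``, ``A`` (Mha), ``D`` (MgC/ha), ``C`` (MtC) and, once derived,
``S`` (MtC/a, absent for the first year of each group). Cumulative sinks
over a window are stock differences, so the cumulative sink 2019-2060 is
C_2060 - C_2018 (42 annual sinks); negative values are legal and never
clipped (a harvested stand can end a window below where it started).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "carbon_stock",
    "annual_sink",
    "cumulative_and_average",
    "growth_statistics",
    "aggregate",
    "national_stock",
    "round_reported",
]

_GROUP_COLS = ["species", "forest_class"]


def round_reported(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of the printed tables."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def carbon_stock(density: float, area: float) -> float:
    """Vegetation carbon stock, MtC, from density (MgC/ha) and area (Mha)."""
    if density < 0 or area < 0:
        raise ValueError(f"density and area must be >= 0 (D={density}, A={area})")
    return density * area


def _group_cols(series: pd.DataFrame) -> list[str]:
    return [c for c in _GROUP_COLS + ["origin"] if c in series.columns]


def annual_sink(series: pd.DataFrame) -> pd.DataFrame:
    """Append the annual-sink column ``S`` as first differences of ``C``.

    Each (species, forest_class) group must cover consecutive years; a gap
    would silently turn a multi-year stock change into one year's sink, so
    it raises instead. The first year of each group has no sink (NaN).
    """
    cols = _group_cols(series)
    out = series.sort_values(cols + ["year"]).copy() if cols else series.sort_values("year").copy()
    grouped = out.groupby(cols) if cols else [(None, out)]
    for key, g in grouped:
        years = g["year"].to_numpy()
        if len(years) >= 2 and not np.all(np.diff(years) == 1):
            raise ValueError(f"year gap in series {key}: {years}")
    if cols:
        out["S"] = out.groupby(cols)["C"].diff()
    else:
        out["S"] = out["C"].diff()
    return out


def cumulative_and_average(
    series: pd.Series | pd.DataFrame, y0: int, y1: int
) -> tuple[float, float]:
    """Cumulative sink over [y0, y1] and its annual average.

    The cumulative sink is the stock difference C_{y1} - C_{y0-1}; the
    average divides by the y1 - y0 + 1 sink years (2019-2060 spans 42).
    Accepts a year-indexed stock Series or a single-group StockSeries
    frame.
    """
    if isinstance(series, pd.DataFrame):
        series = series.set_index("year")["C"]
    if y0 > y1:
        raise ValueError(f"empty window [{y0}, {y1}]")
    for year in (y0 - 1, y1):
        if year not in series.index:
            raise ValueError(f"year {year} outside the series horizon")
    cumulative = float(series.loc[y1] - series.loc[y0 - 1])
    return cumulative, cumulative / (y1 - y0 + 1)


def growth_statistics(c_start: float, c_end: float, n_years: int) -> tuple[float, float]:
    """Percent change and mean annual (geometric) growth rate, both in %."""
    if c_start <= 0:
        raise ValueError(f"starting stock must be positive, got {c_start}")
    if n_years <= 0:
        raise ValueError(f"n_years must be positive, got {n_years}")
    ratio = c_end / c_start
    return (ratio - 1.0) * 100.0, (ratio ** (1.0 / n_years) - 1.0) * 100.0


def aggregate(series: pd.DataFrame, by: str = "national") -> pd.DataFrame:
    """Aggregate a stock series across species and/or classes.

    ``by`` is ``"species"``, ``"forest_class"`` or ``"national"``. Areas
    and stocks sum; the aggregate density is total stock over total area,
    not a mean of densities. An existing sink column is re-derived.
    """
    keys = {
        "species": ["species", "year"],
        "forest_class": ["forest_class", "year"],
        "national": ["year"],
    }
    if by not in keys:
        raise ValueError(f"unknown aggregation level {by!r}")
    out = series.groupby(keys[by], as_index=False)[["A", "C"]].sum()
    out["D"] = out["C"] / out["A"]
    if "S" in series.columns:
        if by == "national":
            out = out.sort_values("year")
            out["S"] = out["C"].diff()
        else:
            out = annual_sink(out.drop(columns="S", errors="ignore"))
    return out


def national_stock(series: pd.DataFrame) -> pd.Series:
    """National year-indexed stock series, MtC."""
    return aggregate(series, "national").set_index("year")["C"]
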