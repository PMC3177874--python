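"""Zonal statistics, class flux totals, CVs and transect extraction.

These are the aggregation steps that turn per-cell flux maps into the
familiar report tables: per-zone area / min / max / mean / standard
deviation over a categorical zone layer or a polygon set, class totals in
Tg C yr^-1, sample coefficients of variation, and short straight-line
transects of grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy

from .rasters_io import COVER_NAMES, LandCoverMap, RasterGrid, check_aligned

__all__ = [
    "TABLE_COLUMNS",
    "ZonalSummaryTable",
    "zonal_summary",
    "class_total_flux",
    "coefficient_of_variation",
    "TransectSeries",
    "transect_extract",
]

TABLE_COLUMNS = [
    "Class Name",
    "Area (m2)",
    "Minimum",
    "Maximum",
    "Mean",
    "Standard Deviation",
]


@dataclass
class ZonalSummaryTable:
    """Per-zone summary rows; renders to a CSV with the standard header."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table.columns) != TABLE_COLUMNS:
            raise ValueError(f"expected columns {TABLE_COLUMNS}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ZonalSummaryTable":
        return cls(pd.read_csv(path))

    def row(self, name: str) -> pd.Series:
        hits = self.table[self.table["Class Name"] == name]
        if hits.empty:
            raise KeyError(name)
        return hits.iloc[0]


def _zone_stats(values: np.ndarray, cell_area: float) -> dict:
    n = values.size
    if n == 0:
        return {"Area (m2)": 0.0, "Minimum": np.nan, "Maximum": np.nan,
                "Mean": np.nan, "Standard Deviation": np.nan}
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return {
        "Area (m2)": n * cell_area,
        "Minimum": float(values.min()),
        "Maximum": float(values.max()),
        "Mean": float(values.mean()),
        "Standard Deviation": sd,
    }


def zonal_summary(flux: RasterGrid, zones) -> ZonalSummaryTable:
    """Summarize a flux grid over zones.

    ``zones`` is either a :class:`LandCoverMap` (one row per class code
    present) or a list of ``(name, polygon)`` pairs, rasterized by
    cell-center inclusion.  Nodata flux cells are excluded everywhere; an
    empty zone yields a zero-area row with NaN statistics.  Standard
    deviations are sample (n-1) throughout.
    """
    rows = []
    cell_area = flux.cell_area_m2
    flux_ok = ~flux.mask
    if isinstance(zones, LandCoverMap):
        if not check_aligned([flux, zones.grid]):
            raise ValueError("flux and zone grids are not aligned")
        for code in sorted(np.unique(zones.grid.valid_values())):
            sel = (zones.grid.values == code) & flux_ok
            name = COVER_NAMES.get(int(code), str(int(code)))
            rows.append({"Class Name": name, **_zone_stats(flux.values[sel], cell_area)})
    else:
        xx, yy = flux.cell_centers()
        for name, poly in zones:
            inside = contains_xy(poly, xx.ravel(), yy.ravel()).reshape(flux.shape)
            sel = inside & flux_ok
            rows.append({"Class Name": name, **_zone_stats(flux.values[sel], cell_area)})
    return ZonalSummaryTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


def class_total_flux(area_m2: float, mean_flux_g_m2: float) -> float:
    """Class total in Tg C yr^-1 from zone area and mean areal flux."""
    if area_m2 < 0:
        raise ValueError("area must be nonnegative")
    return area_m2 * mean_flux_g_m2 * 1e-12


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: 100 * sd(n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * np.std(v, ddof=1) / mean)


@dataclass
class TransectSeries:
    """Flux series sampled at collinear grid cells along a transect."""

    cells: list[tuple[int, int]]
    monthly: np.ndarray  # (n_months, n_points)
    years: list[int]

    @property
    def annual(self) -> np.ndarray:
        """(n_years, n_points) annual totals."""
        return self.monthly.reshape(len(self.years), 12, -1).sum(axis=1)


def transect_extract(fluxes, endpoints, n_points: int = 4, variable: str = "npp") -> TransectSeries:
    """Sample a flux series at n equally spaced cells on a straight line.

    ``fluxes`` is a simulate.FluxSeries; ``endpoints`` two (x, y) map
    coordinates inside the grid.  The cells containing the n interpolated
    points are returned with their monthly and annual series (coincident
    endpoints degenerate to the same cell repeated).
    """
    template = fluxes.template
    (x0, y0), (x1, y1) = endpoints
    cells = []
    for f in np.linspace(0.0, 1.0, n_points):
        x = x0 + f * (x1 - x0)
        y = y0 + f * (y1 - y0)
        cells.append(template.cell_of(x, y))  # raises if outside the grid
    arr = {"npp": fluxes.npp, "rh": fluxes.rh, "nep": fluxes.nep}[variable]
    monthly = np.stack([arr[:, r, c] for r, c in cells], axis=1)
    return TransectSeries(cells, monthly, fluxes.years)
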