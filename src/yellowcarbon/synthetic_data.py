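"""Seeded synthetic Yellowstone-like landscape and monthly forcing record.

The generator emulates the structure of the real model inputs — a clustered
NLCD-like land-cover mosaic dominated by evergreen forest and sagebrush
shrubland, five soil texture classes, an elevation field inside the park's
1540-3760 m range, 1988-style burn perimeters, per-class MODIS-EVI seasonal
curves, PRISM-like monthly temperature/precipitation normals (January mean
-11.4 degC, July mean 10.8 degC, 56.3 cm yr^-1 at the reference elevation),
a smooth seasonal solar-irradiance curve, and post-fire coarse-woody-debris
maps in the two-regime <=60 / >=60 t biomass ha^-1 pattern.

Everything is a deterministic function of a single integer seed: one
:class:`numpy.random.SeedSequence` spawns independent sub-streams for the
landscape, the forcing record and the CWD maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box
from shapely import contains_xy, unary_union

from .rasters_io import (
    COVER_CODES,
    INT_NODATA,
    LandCoverMap,
    RasterGrid,
    SoilMap,
    TEXTURE_CODES,
)

__all__ = [
    "LandscapeConfig",
    "ClimateConfig",
    "ForcingStack",
    "generate_landscape",
    "generate_forcing",
    "generate_cwd_maps",
    "default_scene",
]

# Land-cover mix approximating the study area's class areas (evergreen forest
# and shrubland together ~83% of land).
DEFAULT_CLASS_FRACTIONS = {
    "evergreen_forest": 0.435,
    "shrubland": 0.395,
    "grassland": 0.130,
    "water": 0.030,
    "barren": 0.005,
    "wooded_grassland": 0.004,
    "cultivation": 0.001,
}

DEFAULT_TEXTURE_FRACTIONS = {
    "medium_coarse": 0.560,
    "medium": 0.225,
    "coarse": 0.205,
    "medium_fine": 0.007,
    "fine": 0.003,
}

# Per-class EVI seasonal envelope: (winter floor, summer peak).  Evergreen
# conifers keep a green winter floor; grassland/shrubland drop to near zero
# under snow; open water is slightly negative.
EVI_CURVES = {
    "water": (-0.05, -0.02),
    "barren": (0.02, 0.08),
    "grassland": (0.04, 0.35),
    "evergreen_forest": (0.15, 0.42),
    "shrubland": (0.05, 0.28),
    "mixed_forest": (0.12, 0.48),
    "cultivation": (0.05, 0.50),
    "wooded_grassland": (0.10, 0.45),
    "deciduous_forest": (0.05, 0.55),
}

_EVI_PEAK_MONTH = 6.2  # early-to-mid July greenness maximum
_EVI_WIDTH_MONTHS = 1.8


@dataclass
class LandscapeConfig:
    """Scene geometry, class mix and burn layout.

    The default scene is 100x100 cells at 250 m (~625 km^2), a desk-scale
    stand-in for the park grid.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 250.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    texture_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_FRACTIONS)
    )
    elev_range_m: tuple[float, float] = (1600.0, 3000.0)
    n_fires: int = 3
    burned_forest_fraction: float = 0.25
    correlation_length_cells: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if any(f < 0 or f > 1 for f in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        lo, hi = self.elev_range_m
        if not (1540.0 <= lo < hi <= 3760.0):
            raise ValueError("elevation range must lie within [1540, 3760] m")


@dataclass
class ClimateConfig:
    """Station normals and variability knobs for the weather generator."""

    jan_mean_t: float = -11.4  # degC at reference elevation
    jul_mean_t: float = 10.8
    annual_precip_cm: float = 56.3
    interannual_t_sd: float = 1.0  # degC, year-month anomaly
    interannual_p_cv: float = 0.15
    lapse_c_per_km: float = -6.5
    precip_lapse_per_km: float = 0.20  # fractional increase per km above ref
    reference_elevation_m: float = 2000.0
    solar_mean_mj: float = 210.0  # monthly PAR-scale irradiance, MJ m^-2
    solar_amplitude_mj: float = 150.0
    burn_evi_factor: float = 0.65  # EVI suppression on burned forest cells

    def validate(self) -> None:
        if self.jul_mean_t <= self.jan_mean_t:
            raise ValueError("July mean temperature must exceed January mean")
        if self.annual_precip_cm < 0:
            raise ValueError("annual precipitation must be nonnegative")


@dataclass
class ForcingStack:
    """Monthly EVI, air temperature, precipitation and solar irradiance.

    Arrays are shaped (n_months, n_rows, n_cols) with month 0 = January of
    ``years[0]``; ``template`` carries the shared georeferencing.
    """

    years: list[int]
    evi: np.ndarray
    temp_c: np.ndarray
    precip_mm: np.ndarray
    solar_mj: np.ndarray
    template: RasterGrid

    def __post_init__(self) -> None:
        n = 12 * len(self.years)
        for name in ("evi", "temp_c", "precip_mm", "solar_mj"):
            arr = getattr(self, name)
            if arr.shape != (n, *self.template.shape):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n}, ...)")

    @property
    def n_months(self) -> int:
        return self.evi.shape[0]

    def climatology(self) -> "ForcingStack":
        """Mean-monthly 12-month stack (per calendar month across years)."""

        def clim(a: np.ndarray) -> np.ndarray:
            return a.reshape(len(self.years), 12, *self.template.shape).mean(axis=0)

        return ForcingStack(
            years=[0],
            evi=clim(self.evi),
            temp_c=clim(self.temp_c),
            precip_mm=clim(self.precip_mm),
            solar_mj=clim(self.solar_mj),
            template=self.template,
        )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Standardized spatially-correlated Gaussian field."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=scale, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _classify_by_quantile(f: np.ndarray, fractions: dict[str, float], codes: dict[str, int]) -> np.ndarray:
    """Threshold a continuous field into classes with the requested areas."""
    order = list(fractions)
    out = np.full(f.shape, INT_NODATA, dtype=np.int64)
    flat = f.ravel()
    ranks = np.argsort(flat, kind="stable")
    n = flat.size
    start = 0
    cum = 0.0
    for name in order:
        cum += fractions[name]
        stop = n if name == order[-1] else min(n, int(round(cum * n)))
        out.ravel()[ranks[start:stop]] = codes[name]
        start = stop
    return out


def _fire_polygon(rng: np.random.Generator, cx: float, cy: float, radius: float) -> Polygon:
    """An irregular star-convex burn perimeter around (cx, cy)."""
    n_vert = 24
    theta = np.linspace(0.0, 2 * np.pi, n_vert, endpoint=False)
    wob = gaussian_filter(rng.standard_normal(n_vert), sigma=2.0, mode="wrap")
    wob = wob / (np.abs(wob).max() + 1e-12)
    r = radius * (1.0 + 0.35 * wob)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    poly = Polygon(zip(xs, ys))
    return poly if poly.is_valid else poly.buffer(0)


def generate_landscape(cfg: LandscapeConfig):
    """Generate (land cover, soils, elevation, fire perimeters) for a scene.

    Cover and texture classes come from smoothed random fields thresholded at
    the configured area quantiles, so classes are spatially clustered and the
    realized fractions match the request up to rounding.  Fire perimeters are
    irregular polygons centered on forested cells, sized so the burned share
    of forest area approximates ``burned_forest_fraction``.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng_cover, rng_soil, rng_elev, rng_fire = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    shape = (cfg.n_rows, cfg.n_cols)
    scale = cfg.correlation_length_cells

    cover_vals = _classify_by_quantile(
        _smooth_field(rng_cover, shape, scale), cfg.class_fractions, COVER_CODES
    )
    template = RasterGrid(
        np.zeros(shape), origin_x=0.0, origin_y=cfg.n_rows * cfg.cell_size,
        cell_size=cfg.cell_size,
    )
    cover = LandCoverMap(template.like(cover_vals))

    texture_vals = _classify_by_quantile(
        _smooth_field(rng_soil, shape, scale * 1.5), cfg.texture_fractions, TEXTURE_CODES
    )
    depth01 = _smooth_field(rng_soil, shape, scale * 1.5)
    depth01 = (depth01 - depth01.min()) / (np.ptp(depth01) + 1e-12)
    rooting = np.clip(0.5 + 1.5 * depth01, 0.5, 2.0)
    soil = SoilMap(template.like(texture_vals), template.like(rooting))

    e = _smooth_field(rng_elev, shape, scale * 2.0)
    e01 = (e - e.min()) / (np.ptp(e) + 1e-12)
    lo, hi = cfg.elev_range_m
    elevation = template.like(lo + (hi - lo) * e01)

    # Burn perimeters sized against the forested area.
    forest = np.isin(cover_vals, [COVER_CODES["evergreen_forest"],
                                  COVER_CODES["mixed_forest"],
                                  COVER_CODES["deciduous_forest"]])
    forest_area = forest.sum() * template.cell_area_m2
    fires: list[Polygon] = []
    if cfg.n_fires > 0 and forest_area > 0:
        target = cfg.burned_forest_fraction * forest_area / cfg.n_fires
        radius = np.sqrt(target / np.pi)
        rows, cols = np.nonzero(forest)
        bounds = box(0.0, 0.0, cfg.n_cols * cfg.cell_size, cfg.n_rows * cfg.cell_size)
        for _ in range(cfg.n_fires):
            i = rng_fire.integers(len(rows))
            cx, cy = template.cell_center(int(rows[i]), int(cols[i]))
            poly = _fire_polygon(rng_fire, cx, cy, radius).intersection(bounds)
            if not poly.is_empty:
                fires.append(poly)
    return cover, soil, elevation, fires


def generate_forcing(
    landscape,
    climate_cfg: ClimateConfig,
    years,
    seed: int,
) -> ForcingStack:
    """Monthly forcing record for the scene.

    Temperature follows a sinusoid between the January/July normals with
    -6.5 degC km^-1 (default) lapse cooling by elevation plus seeded
    year-month anomalies; precipitation distributes the annual normal over a
    mild late-spring peak with lognormal interannual noise; EVI follows the
    per-class unimodal summer curve damped at high elevation, with formerly
    forested cells inside burn perimeters suppressed by ``burn_evi_factor``
    (regrowing sapling stands are less green than the mature forest they
    replaced); irradiance is a smooth seasonal curve identical across the grid.
    """
    climate_cfg.validate()
    cover, soil, elevation, fires = landscape
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    root = np.random.SeedSequence(seed)
    rng_t, rng_p, rng_e, rng_s = (np.random.default_rng(s) for s in root.spawn(4))

    template = cover.grid
    shape = template.shape
    n_months = 12 * len(years)
    elev = elevation.values
    dz_km = (elev - climate_cfg.reference_elevation_m) / 1000.0

    mid = 0.5 * (climate_cfg.jan_mean_t + climate_cfg.jul_mean_t)
    amp = 0.5 * (climate_cfg.jul_mean_t - climate_cfg.jan_mean_t)
    months = np.arange(12)
    t_season = mid - amp * np.cos(2 * np.pi * (months - 0.3) / 12.0)  # min in Jan, max in Jul

    p_base = climate_cfg.annual_precip_cm * 10.0 / 12.0  # mm month^-1
    p_season = p_base * (1.0 + 0.25 * np.cos(2 * np.pi * (months - 4.5) / 12.0))
    p_season *= (climate_cfg.annual_precip_cm * 10.0) / p_season.sum()
    p_elev = np.clip(1.0 + climate_cfg.precip_lapse_per_km * dz_km, 0.3, None)
    p_cv = climate_cfg.interannual_p_cv
    p_sigma = np.sqrt(np.log(1.0 + p_cv**2)) if p_cv > 0 else 0.0

    s_season = climate_cfg.solar_mean_mj + climate_cfg.solar_amplitude_mj * np.cos(
        2 * np.pi * (months - 5.7) / 12.0
    )

    evi_noise = 0.04 * _smooth_field(rng_e, shape, 4.0)
    evi_elev = np.clip(1.0 - 0.25 * (elev - 2000.0) / 1000.0, 0.4, 1.1)
    floor_map = np.zeros(shape)
    peak_map = np.zeros(shape)
    for name, code in COVER_CODES.items():
        floor, peak = EVI_CURVES[name]
        m = cover.values == code
        floor_map[m] = floor
        peak_map[m] = peak
    if fires:
        burned = contains_xy(
            unary_union(fires), *(c.ravel() for c in template.cell_centers())
        ).reshape(shape)
        burned &= np.isin(cover.values, [COVER_CODES["evergreen_forest"],
                                         COVER_CODES["mixed_forest"],
                                         COVER_CODES["deciduous_forest"]])
        floor_map = np.where(burned, floor_map * climate_cfg.burn_evi_factor, floor_map)
        peak_map = np.where(burned, peak_map * climate_cfg.burn_evi_factor, peak_map)

    temp = np.empty((n_months,) + shape)
    precip = np.empty_like(temp)
    evi = np.empty_like(temp)
    solar = np.empty_like(temp)
    for yi in range(len(years)):
        for m in range(12):
            k = 12 * yi + m
            anomaly = rng_t.normal(0.0, climate_cfg.interannual_t_sd)
            temp[k] = t_season[m] + climate_cfg.lapse_c_per_km * dz_km + anomaly
            p_mult = np.exp(rng_p.normal(-0.5 * p_sigma**2, p_sigma)) if p_sigma > 0 else 1.0
            precip[k] = np.clip(p_season[m] * p_elev * p_mult, 0.0, None)
            bump = np.exp(-0.5 * ((m - _EVI_PEAK_MONTH) / _EVI_WIDTH_MONTHS) ** 2)
            raw = floor_map + (peak_map - floor_map) * bump * evi_elev
            raw = raw + evi_noise * bump + rng_e.normal(0.0, 0.01, shape)
            evi[k] = np.clip(raw, -0.2, 1.0)
            solar[k] = s_season[m] * rng_s.normal(1.0, 0.03)
    return ForcingStack(years=years, evi=evi, temp_c=temp, precip_mm=precip,
                        solar_mj=solar, template=template)


def generate_cwd_maps(landscape, fire_perimeters, seed: int,
                      high_regime_weight: float = 0.5):
    """Post-fire coarse-woody-debris maps over the burn perimeters.

    Downed biomass (t ha^-1) is drawn from a two-regime mixture straddling
    the 60 t ha^-1 classification break (low regime ~35, high ~95 t ha^-1);
    the standing-dead fraction is Beta-distributed in [0, 0.8].  Cells outside
    every perimeter, or not forested, carry zero debris.
    """
    cover, soil, elevation, _ = landscape
    template = cover.grid
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    shape = template.shape

    burned = np.zeros(shape, dtype=bool)
    if fire_perimeters:
        union = unary_union(fire_perimeters)
        xx, yy = template.cell_centers()
        burned = contains_xy(union, xx.ravel(), yy.ravel()).reshape(shape)
    forest = np.isin(cover.values, [COVER_CODES["evergreen_forest"],
                                    COVER_CODES["mixed_forest"],
                                    COVER_CODES["deciduous_forest"]])
    support = burned & forest

    downed = np.zeros(shape)
    standing_frac = np.zeros(shape)
    n = int(support.sum())
    if n:
        high = rng.random(n) < high_regime_weight
        low_draw = np.clip(rng.normal(35.0, 12.0, n), 1.0, 59.0)
        high_draw = np.clip(rng.normal(95.0, 25.0, n), 61.0, 180.0)
        downed[support] = np.where(high, high_draw, low_draw)
        standing_frac[support] = 0.8 * rng.beta(2.0, 5.0, n)
    return template.like(downed), template.like(standing_frac)


def default_scene(seed: int = 0, years=range(2000, 2007), cfg: LandscapeConfig | None = None,
                  climate: ClimateConfig | None = None):
    """The default desk-scale scene: landscape + 7-year forcing + CWD maps."""
    cfg = cfg or LandscapeConfig(seed=seed)
    climate = climate or ClimateConfig()
    landscape = generate_landscape(cfg)
    forcing = generate_forcing(landscape, climate, years, seed=seed + 1)
    cwd = generate_cwd_maps(landscape, landscape[3], seed=seed + 2)
    return landscape, forcing, cwd


# ---------------------------------------------------------------------------
# Forcing/layout disk I/O shared with the CLI: one GeoTIFF per variable per
# month, named {var}_{YYYY}_{MM}.tif alongside the static landscape rasters.

_FORCING_VARS = {"evi": "evi", "temp": "temp_c", "precip": "precip_mm", "solar": "solar_mj"}


def write_forcing(stack: ForcingStack, out_dir) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    for var, attr in _FORCING_VARS.items():
        arr = getattr(stack, attr)
        for yi, year in enumerate(stack.years):
            for m in range(12):
                from .rasters_io import write_raster

                grid = stack.template.like(arr[12 * yi + m])
                write_raster(grid, os.path.join(out_dir, f"{var}_{year:04d}_{m + 1:02d}.tif"))


def read_forcing(in_dir, years) -> ForcingStack:
    import os

    from .rasters_io import read_raster

    years = list(years)
    arrays = {}
    template = None
    for var, attr in _FORCING_VARS.items():
        months = []
        for year in years:
            for m in range(12):
                g = read_raster(os.path.join(in_dir, f"{var}_{year:04d}_{m + 1:02d}.tif"))
                template = template or g
                months.append(g.values)
        arrays[attr] = np.stack(months)
    return ForcingStack(years=years, template=template, **arrays)
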