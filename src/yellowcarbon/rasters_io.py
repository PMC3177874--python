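"""Georeferenced raster grids: the common currency of every model stage.

A :class:`RasterGrid` is a rectangular 2-D field with a top-left map origin,
square cells, a coordinate-reference identifier and a nodata sentinel.  Grids
are stored on disk as single-band GeoTIFFs (pixel scale, tiepoint and nodata
carried in the standard GeoTIFF/GDAL tags); fire perimeters travel as GeoJSON.

Float grids represent nodata internally as NaN; integer grids (land-cover or
soil-texture codes) keep an explicit sentinel value.  Two grids are *aligned*
iff shape, origin, cell size and CRS identifier all agree — every simulation
stage refuses unaligned stacks.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

__all__ = [
    "RasterGrid",
    "LandCoverMap",
    "SoilMap",
    "COVER_CODES",
    "COVER_NAMES",
    "TEXTURE_CODES",
    "TEXTURE_NAMES",
    "INT_NODATA",
    "read_raster",
    "write_raster",
    "aggregate_majority",
    "check_aligned",
    "read_fire_perimeters",
    "write_fire_perimeters",
]

# Land-cover class codes (NLCD-like thematic legend).  Majority ties break to
# the lowest code, so the ordering here is part of the contract.
COVER_CODES = {
    "water": 0,
    "barren": 1,
    "grassland": 2,
    "evergreen_forest": 3,
    "shrubland": 4,
    "mixed_forest": 5,
    "cultivation": 6,
    "wooded_grassland": 7,
    "deciduous_forest": 8,
}
COVER_NAMES = {v: k for k, v in COVER_CODES.items()}

# Soil texture classes, coarse (rhyolitic, low water holding) to fine.
TEXTURE_CODES = {
    "coarse": 0,
    "medium_coarse": 1,
    "medium": 2,
    "medium_fine": 3,
    "fine": 4,
}
TEXTURE_NAMES = {v: k for k, v in TEXTURE_CODES.items()}

INT_NODATA = -9999

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A single-band georeferenced grid.

    ``values[0, 0]`` is the NW cell; rows increase southward.  ``origin_x``,
    ``origin_y`` are the map coordinates of the grid's top-left corner and
    ``cell_size`` is the (square) pixel edge in meters.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 250.0
    crs_id: str = "synthetic-local"
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if np.issubdtype(self.values.dtype, np.integer) and (
            isinstance(self.nodata, float) and math.isnan(self.nodata)
        ):
            self.nodata = INT_NODATA

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds no data."""
        if self.is_integer:
            return self.values == int(self.nodata)
        m = np.isnan(self.values)
        if not math.isnan(self.nodata):
            m |= self.values == self.nodata
        return m

    @property
    def cell_area_m2(self) -> float:
        # Flat geometry: projection distortion is ignored by design.
        return float(self.cell_size) ** 2

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("shape mismatch with template grid")
        nodata = INT_NODATA if np.issubdtype(np.asarray(values).dtype, np.integer) else float("nan")
        return replace(self, values=np.asarray(values), nodata=nodata)

    def full_like(self, fill: float, dtype=np.float64) -> "RasterGrid":
        return self.like(np.full(self.shape, fill, dtype=dtype))

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of all cell centers as (X, Y) 2-D arrays."""
        nr, nc = self.shape
        xs = self.origin_x + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class LandCoverMap:
    """Integer land-cover class grid using :data:`COVER_CODES`."""

    grid: RasterGrid

    def __post_init__(self) -> None:
        if not self.grid.is_integer:
            raise ValueError("land-cover grid must hold integer class codes")
        bad = np.setdiff1d(self.grid.valid_values(), list(COVER_CODES.values()))
        if bad.size:
            raise ValueError(f"unknown land-cover codes: {sorted(bad.tolist())}")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    def class_mask(self, name: str) -> np.ndarray:
        return self.grid.values == COVER_CODES[name]


@dataclass
class SoilMap:
    """Soil texture class codes plus plant rooting depth (m)."""

    texture: RasterGrid
    rooting_depth_m: RasterGrid

    def __post_init__(self) -> None:
        if not check_aligned([self.texture, self.rooting_depth_m]):
            raise ValueError("soil texture and rooting depth grids are not aligned")
        bad = np.setdiff1d(self.texture.valid_values(), list(TEXTURE_CODES.values()))
        if bad.size:
            raise ValueError(f"unknown soil texture codes: {sorted(bad.tolist())}")
        depths = self.rooting_depth_m.valid_values()
        if depths.size and (depths <= 0).any():
            raise ValueError("rooting depth must be positive where land")


def write_raster(grid: RasterGrid, path: str | os.PathLike) -> None:
    """Write a grid as a single-band GeoTIFF.

    Integer grids are stored as int32 (bit-exact round trip); float grids as
    float64 with NaN nodata replaced by the sentinel in the GDAL nodata tag.
    """
    if grid.is_integer:
        data = grid.values.astype(np.int32)
        nodata_str = str(int(grid.nodata))
    else:
        data = grid.values.astype(np.float64).copy()
        data[np.isnan(data)] = float(INT_NODATA)
        nodata_str = str(float(INT_NODATA))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(os.fspath(path), data, extratags=extratags, description=f"crs:{grid.crs_id}")


def read_raster(path: str | os.PathLike) -> RasterGrid:
    """Load a single-band GeoTIFF written by :func:`write_raster` (or any
    single-band GeoTIFF carrying pixel-scale/tiepoint tags)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"unreadable raster format: {path}") from exc
    with tf:
        page = tf.pages[0]
        if len(tf.pages) > 1 or page.samplesperpixel != 1:
            raise ValueError(f"multi-band raster not supported: {path}")
        values = page.asarray()
        tag = page.tags.get(_TAG_PIXEL_SCALE)
        cell = float(tag.value[0]) if tag is not None else 1.0
        tag = page.tags.get(_TAG_TIEPOINT)
        ox, oy = (float(tag.value[3]), float(tag.value[4])) if tag is not None else (0.0, 0.0)
        tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(tag.value) if tag is not None else float(INT_NODATA)
        desc = page.description or ""
        crs_id = desc[4:] if desc.startswith("crs:") else "unknown"
    if np.issubdtype(values.dtype, np.integer):
        return RasterGrid(values.astype(np.int64), ox, oy, cell, crs_id, nodata=int(nodata))
    values = values.astype(np.float64)
    values[values == nodata] = np.nan
    return RasterGrid(values, ox, oy, cell, crs_id, nodata=float("nan"))


def check_aligned(grids: list[RasterGrid], atol: float = 1e-6) -> bool:
    """True iff all grids share shape, origin, cell size and CRS."""
    if not grids:
        raise ValueError("empty grid list")
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or g.crs_id != ref.crs_id:
            return False
        if abs(g.cell_size - ref.cell_size) > atol:
            return False
        if abs(g.origin_x - ref.origin_x) > atol or abs(g.origin_y - ref.origin_y) > atol:
            return False
    return True


def first_unaligned(grids: list[RasterGrid]) -> int | None:
    """Index of the first grid that disagrees with grids[0], or None."""
    for i in range(1, len(grids)):
        if not check_aligned([grids[0], grids[i]]):
            return i
    return None


def aggregate_majority(fine: LandCoverMap, factor: int) -> LandCoverMap:
    """Aggregate a class map by the modal class of each factor x factor block.

    Nodata cells are ignored when counting; all-nodata blocks stay nodata;
    ties break to the lowest class code.  Grids whose dimensions are not
    divisible by ``factor`` are padded with nodata on the south/east edges.
    """
    if factor <= 0:
        raise ValueError("aggregation factor must be >= 1")
    g = fine.grid
    nodata = int(g.nodata)
    nr, nc = g.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), nodata, dtype=np.int64)
    padded[:nr, :nc] = g.values
    blocks = padded.reshape(out_r, factor, out_c, factor)
    codes = sorted(COVER_CODES.values())
    counts = np.stack([(blocks == c).sum(axis=(1, 3)) for c in codes])
    best = np.argmax(counts, axis=0)  # first max -> lowest code wins ties
    out = np.array(codes, dtype=np.int64)[best]
    out[counts.sum(axis=0) == 0] = nodata
    coarse = RasterGrid(
        out,
        origin_x=g.origin_x,
        origin_y=g.origin_y,
        cell_size=g.cell_size * factor,
        crs_id=g.crs_id,
        nodata=nodata,
    )
    return LandCoverMap(coarse)


def write_fire_perimeters(polygons: list, path: str | os.PathLike, names: list[str] | None = None) -> None:
    """Write burn-perimeter polygons as a GeoJSON FeatureCollection."""
    feats = []
    for i, poly in enumerate(polygons):
        props = {"name": names[i] if names else f"fire_{i:02d}"}
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_fire_perimeters(path: str | os.PathLike) -> tuple[list, list[str]]:
    with open(path) as fh:
        fc = json.load(fh)
    polys = [shape(f["geometry"]) for f in fc["features"]]
    names = [f.get("properties", {}).get("name", f"fire_{i:02d}") for i, f in enumerate(fc["features"])]
    return polys, names
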