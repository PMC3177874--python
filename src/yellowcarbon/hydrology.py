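"""Monthly bucket-model soil hydrology: snowpack plus three soil layers.

The profile holds a surface-organic layer (M1, fixed 10 mm capacity), a
topsoil layer (M2, 0.3 m) and a subsoil layer (M3, down to the rooting
depth).  Each month precipitation falls as snow below 0 degC; snow melts at
a degree-month rate; rain plus melt recharges the layers to field capacity
in order, with the surplus percolating out as drainage.  Estimated actual
evapotranspiration (EET) is then drawn from the layers top-down, each layer
yielding in proportion to its relative saturation, never exceeding the
Thornthwaite potential (PET).  Every step conserves water exactly:

    precip = EET + runoff + drainage + d(snowpack) + d(soil storage)

EET/PET feeds the production moisture scalar; the M1+M2 relative saturation
feeds the decomposition moisture factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rasters_io import SoilMap, TEXTURE_NAMES

__all__ = [
    "SoilMoistureState",
    "HydroParams",
    "heat_index",
    "potential_et",
    "layer_capacities",
    "step_water_balance",
]

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], dtype=float)

# Field capacity per meter of soil depth (mm m^-1) by texture class.  Finer
# textures hold more water; the ordering is part of the contract.
DEFAULT_FIELD_CAPACITY_MM_PER_M = {
    "coarse": 100.0,
    "medium_coarse": 125.0,
    "medium": 150.0,
    "medium_fine": 175.0,
    "fine": 200.0,
}


@dataclass
class HydroParams:
    field_capacity_mm_per_m: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_CAPACITY_MM_PER_M)
    )
    m1_capacity_mm: float = 10.0
    topsoil_depth_m: float = 0.3
    melt_coeff_mm_per_c: float = 40.0  # degree-month snowmelt rate
    pet_method: str = "thornthwaite"

    def __post_init__(self) -> None:
        order = ["coarse", "medium_coarse", "medium", "medium_fine", "fine"]
        caps = [self.field_capacity_mm_per_m[k] for k in order]
        if any(c <= 0 for c in caps):
            raise ValueError("field capacities must be positive")
        if any(a >= b for a, b in zip(caps, caps[1:])):
            raise ValueError("capacities must increase from coarse to fine texture")


@dataclass
class SoilMoistureState:
    """Snowpack (mm water equivalent) and per-layer soil water (mm)."""

    snowpack: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "SoilMoistureState":
        return cls(*(np.zeros(shape) for _ in range(4)))

    def copy(self) -> "SoilMoistureState":
        return SoilMoistureState(self.snowpack.copy(), self.m1.copy(),
                                 self.m2.copy(), self.m3.copy())

    def total_soil_water(self) -> np.ndarray:
        return self.m1 + self.m2 + self.m3


def heat_index(temp_climatology: np.ndarray) -> np.ndarray:
    """Thornthwaite annual heat index I from a 12-month temperature series."""
    t = np.asarray(temp_climatology, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("temperature climatology must have 12 leading months")
    return np.sum((np.clip(t, 0.0, None) / 5.0) ** 1.514, axis=0)


def _daylight_hours(latitude: float, month_index: int) -> float:
    decl = 0.409 * np.sin(2 * np.pi * (_MID_MONTH_DOY[month_index] - 81.0) / 365.0)
    phi = np.deg2rad(latitude)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def potential_et(t_month, latitude: float, month_index: int, annual_heat_index) -> np.ndarray:
    """Thornthwaite monthly PET, mm month^-1; zero for frozen months.

    Uses the classic formulation PET = 16 (10 T / I)^a corrected for day
    length and month length.  Temperatures above the warm-regime break
    (26.5 degC) do not occur in this climate and are handled by the same
    formula.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    if not 0 <= month_index <= 11:
        raise ValueError("month_index must be 0-11")
    t = np.asarray(t_month, dtype=float)
    i_heat = np.asarray(annual_heat_index, dtype=float)
    a = 6.75e-7 * i_heat**3 - 7.71e-5 * i_heat**2 + 1.792e-2 * i_heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * np.clip(t, 0.0, None) / np.maximum(i_heat, 1e-12)) ** a
    corr = _daylight_hours(latitude, month_index) / 12.0 * _DAYS_IN_MONTH[month_index] / 30.0
    pet = pet * corr
    return np.where((t <= 0.0) | (i_heat <= 0.0), 0.0, pet)


def layer_capacities(soil: SoilMap, params: HydroParams | None = None):
    """(cap1, cap2, cap3) field capacities in mm for each cell."""
    params = params or HydroParams()
    density = np.zeros(soil.texture.shape)
    for code, name in TEXTURE_NAMES.items():
        density[soil.texture.values == code] = params.field_capacity_mm_per_m[name]
    cap1 = np.full(soil.texture.shape, params.m1_capacity_mm)
    cap2 = density * params.topsoil_depth_m
    cap3 = density * np.clip(soil.rooting_depth_m.values - params.topsoil_depth_m, 0.0, None)
    return cap1, cap2, cap3


def step_water_balance(
    state: SoilMoistureState,
    precip,
    t_month,
    pet,
    params: HydroParams,
    capacities,
):
    """Advance the water balance one month.

    Returns ``(new_state, eet, runoff, drainage)``.  Runoff is not separated
    from deep seepage in this bucket scheme — column overflow is reported as
    drainage and the runoff channel is identically zero (kept in the return
    contract so callers see the full balance).
    """
    cap1, cap2, cap3 = (np.asarray(c, dtype=float) for c in capacities)
    if np.any(cap1 <= 0) or np.any(cap2 < 0) or np.any(cap3 < 0):
        raise ValueError("layer capacities must be positive")
    precip = np.asarray(precip, dtype=float)
    t = np.asarray(t_month, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(precip < 0) or np.any(pet < 0):
        raise ValueError("precipitation and PET must be nonnegative")

    new = state.copy()
    snowfall = np.where(t < 0.0, precip, 0.0)
    rain = precip - snowfall
    new.snowpack = new.snowpack + snowfall
    melt = np.minimum(new.snowpack, params.melt_coeff_mm_per_c * np.clip(t, 0.0, None))
    new.snowpack = new.snowpack - melt

    # Recharge to field capacity, top down; surplus percolates out.
    water = rain + melt
    for m_attr, cap in (("m1", cap1), ("m2", cap2), ("m3", cap3)):
        layer = getattr(new, m_attr)
        add = np.minimum(water, np.clip(cap - layer, 0.0, None))
        setattr(new, m_attr, layer + add)
        water = water - add
    drainage = water

    # EET extraction top down, each layer yielding by relative saturation.
    demand = pet.copy()
    eet = np.zeros_like(demand)
    for m_attr, cap in (("m1", cap1), ("m2", cap2), ("m3", cap3)):
        layer = getattr(new, m_attr)
        with np.errstate(divide="ignore", invalid="ignore"):
            sat = np.where(cap > 0, layer / np.maximum(cap, 1e-300), 0.0)
        take = np.minimum(layer, demand * sat)
        setattr(new, m_attr, layer - take)
        eet = eet + take
        demand = demand - take

    runoff = np.zeros_like(eet)
    return new, eet, runoff, drainage
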