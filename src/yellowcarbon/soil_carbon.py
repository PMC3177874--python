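"""Carbon pools: NPP allocation, litterfall, and the decomposition cascade.

Twelve pools per cell (all g C m^-2): live leaf/root/wood; standing dead
wood and downed coarse woody debris (CWD); surface and soil litter, each
split into metabolic and structural fractions; and active, slow and passive
soil organic matter (SOM).

Monthly NPP is allocated to live tissues (forests put 45% into wood with a
50-year mean residence time; shrubs 20%; herbaceous cover none).  Live pools
shed carbon to litter at 1/turnover rates; dead wood enters the standing
pool and topples into downed CWD.  Dead pools decay first-order with an
abiotic (temperature x moisture) rate scalar, each loss splitting between a
respired CO2 share (heterotrophic respiration, Rh) and a transfer to the
downstream pool.  Carbon is conserved exactly every month:

    d(sum of pools) = NPP - Rh

NEP = NPP - Rh; positive values are atmospheric CO2 sinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rasters_io import COVER_CODES, COVER_NAMES

__all__ = [
    "POOL_NAMES",
    "DEAD_POOLS",
    "CarbonParams",
    "CarbonPoolState",
    "allocation_shares",
    "allocate_npp",
    "litterfall",
    "abiotic_scalar",
    "step_decomposition",
    "step_month_carbon",
    "net_ecosystem_production",
    "aboveground_npp",
    "litter_matrix",
    "decomp_matrices",
]

POOL_NAMES = [
    "live_leaf",
    "live_root",
    "live_wood",
    "standing_dead_wood",
    "downed_cwd",
    "litter_surface_metabolic",
    "litter_surface_structural",
    "litter_soil_metabolic",
    "litter_soil_structural",
    "soil_active",
    "soil_slow",
    "soil_passive",
]
_IDX = {name: i for i, name in enumerate(POOL_NAMES)}
DEAD_POOLS = POOL_NAMES[3:]

FOREST_CLASSES = {"evergreen_forest", "mixed_forest", "deciduous_forest", "wooded_grassland"}
SHRUB_CLASSES = {"shrubland"}
HERBACEOUS_CLASSES = {"grassland", "cultivation"}
NO_WOOD_CLASSES = {"water", "barren", "grassland", "cultivation"}


@dataclass
class CarbonParams:
    """Turnover times, allocation ratios and transfer/respiration fractions.

    ``turnover_yr`` are mean residence times at reference abiotic conditions
    (scalar = 1).  Each dead pool's respired fraction plus its transfer
    fractions sums to 1, so mass conservation holds by construction.
    Standing dead wood only topples into downed CWD (no direct Rh) at a rate
    independent of the abiotic scalar.
    """

    tau_wood_yr: float = 50.0
    alpha_wood_forest: float = 0.45
    alpha_wood_shrub: float = 0.20
    leaf_fraction_of_soft: float = 0.5  # leaf:root split of non-wood NPP
    leaf_turnover_yr: float = 2.0
    root_turnover_yr: float = 3.0
    metabolic_fraction: float = 0.5  # metabolic share of leaf/root litter
    q10: float = 2.0
    t_ref_c: float = 20.0
    turnover_yr: dict[str, float] = field(default_factory=lambda: {
        "standing_dead_wood": 100.0,
        "downed_cwd": 40.0,
        "litter_surface_metabolic": 0.5,
        "litter_surface_structural": 3.0,
        "litter_soil_metabolic": 0.5,
        "litter_soil_structural": 3.0,
        "soil_active": 1.5,
        "soil_slow": 25.0,
        "soil_passive": 1000.0,
    })
    # pool -> (respired fraction, {target: transfer fraction})
    transfers: dict[str, tuple[float, dict[str, float]]] = field(default_factory=lambda: {
        "standing_dead_wood": (0.0, {"downed_cwd": 1.0}),
        "downed_cwd": (0.55, {"soil_active": 0.45}),
        "litter_surface_metabolic": (0.55, {"soil_active": 0.45}),
        "litter_surface_structural": (0.55, {"soil_active": 0.45}),
        "litter_soil_metabolic": (0.55, {"soil_active": 0.45}),
        "litter_soil_structural": (0.55, {"soil_active": 0.45}),
        "soil_active": (0.30, {"soil_slow": 0.70}),
        "soil_slow": (0.55, {"soil_active": 0.42, "soil_passive": 0.03}),
        "soil_passive": (1.0, {}),
    })

    def __post_init__(self) -> None:
        for pool in DEAD_POOLS:
            resp, targets = self.transfers[pool]
            total = resp + sum(targets.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{pool}: respired + transfer fractions sum to {total}")
            if not 0.0 <= resp <= 1.0 or any(not 0.0 <= f <= 1.0 for f in targets.values()):
                raise ValueError(f"{pool}: fractions must lie in [0, 1]")
            if self.turnover_yr[pool] <= 0:
                raise ValueError(f"{pool}: turnover must be positive")

    def monthly_rate(self, pool: str) -> float:
        return 1.0 / (12.0 * self.turnover_yr[pool])


@dataclass
class CarbonPoolState:
    """Per-cell carbon pools, g C m^-2; every pool is nonnegative."""

    arrays: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, shape) -> "CarbonPoolState":
        return cls({name: np.zeros(shape) for name in POOL_NAMES})

    @classmethod
    def from_array(cls, stacked: np.ndarray, shape) -> "CarbonPoolState":
        return cls({name: stacked[i].reshape(shape).copy() for i, name in enumerate(POOL_NAMES)})

    def __getattr__(self, name):
        arrays = object.__getattribute__(self, "arrays")
        if name in arrays:
            return arrays[name]
        raise AttributeError(name)

    def __setattr__(self, name, value):
        if name == "arrays":
            object.__setattr__(self, name, value)
        else:
            self.arrays[name] = value

    def copy(self) -> "CarbonPoolState":
        return CarbonPoolState({k: v.copy() for k, v in self.arrays.items()})

    def as_array(self) -> np.ndarray:
        """(12, n_cells) stack in :data:`POOL_NAMES` order."""
        return np.stack([self.arrays[n].ravel() for n in POOL_NAMES])

    def total(self) -> np.ndarray:
        return sum(self.arrays[n] for n in POOL_NAMES)

    def total_dead(self) -> np.ndarray:
        return sum(self.arrays[n] for n in DEAD_POOLS)


def allocation_shares(cover_values: np.ndarray, params: CarbonParams):
    """(leaf, root, wood) NPP shares per cell from the land-cover code."""
    cv = np.atleast_1d(np.asarray(cover_values))
    known = np.array(sorted(COVER_NAMES))
    bad = np.setdiff1d(cv[cv >= 0], known)
    if bad.size:
        raise ValueError(f"unknown land-cover codes: {sorted(bad.tolist())}")
    wood = np.zeros(cv.shape, dtype=float)
    for name in FOREST_CLASSES:
        wood[cv == COVER_CODES[name]] = params.alpha_wood_forest
    for name in SHRUB_CLASSES:
        wood[cv == COVER_CODES[name]] = params.alpha_wood_shrub
    leaf = (1.0 - wood) * params.leaf_fraction_of_soft
    root = 1.0 - wood - leaf
    return leaf, root, wood


def allocate_npp(npp, cover_values, params: CarbonParams):
    """Split monthly NPP into (leaf, root, wood) increments, conserving it exactly."""
    npp = np.asarray(npp, dtype=float)
    if np.any(npp < 0):
        raise ValueError("NPP increments must be nonnegative")
    leaf_s, root_s, wood_s = allocation_shares(cover_values, params)
    d_wood = npp * wood_s
    d_leaf = npp * leaf_s
    d_root = npp - d_wood - d_leaf
    return d_leaf, d_root, d_wood


def litterfall(state: CarbonPoolState, params: CarbonParams):
    """Monthly shed fluxes from the live pools.

    Returns ``(shed_leaf, shed_root, shed_wood)``, each pool shedding a
    linear 1/(12 * turnover) share per month — live wood at 1/tau = 0.02
    yr^-1 feeds the standing dead pool.
    """
    g_leaf = 1.0 / (12.0 * params.leaf_turnover_yr)
    g_root = 1.0 / (12.0 * params.root_turnover_yr)
    g_wood = 1.0 / (12.0 * params.tau_wood_yr)
    return state.live_leaf * g_leaf, state.live_root * g_root, state.live_wood * g_wood


def _apply_litterfall(state: CarbonPoolState, shed, params: CarbonParams) -> None:
    shed_leaf, shed_root, shed_wood = shed
    mf = params.metabolic_fraction
    state.live_leaf = state.live_leaf - shed_leaf
    state.live_root = state.live_root - shed_root
    state.live_wood = state.live_wood - shed_wood
    state.litter_surface_metabolic = state.litter_surface_metabolic + mf * shed_leaf
    state.litter_surface_structural = state.litter_surface_structural + (1 - mf) * shed_leaf
    state.litter_soil_metabolic = state.litter_soil_metabolic + mf * shed_root
    state.litter_soil_structural = state.litter_soil_structural + (1 - mf) * shed_root
    state.standing_dead_wood = state.standing_dead_wood + shed_wood


def abiotic_scalar(t_soil, moisture_ratio, params: CarbonParams | None = None) -> np.ndarray:
    """Decomposition rate scalar: Q10 temperature factor times moisture factor.

    Equals 1 at the 20 degC reference with a saturated profile; the moisture
    factor 0.25 + 0.75 * m keeps a floor of microbial activity in dry soil.
    """
    params = params or CarbonParams()
    t_fac = params.q10 ** ((np.asarray(t_soil, dtype=float) - params.t_ref_c) / 10.0)
    m_fac = 0.25 + 0.75 * np.clip(np.asarray(moisture_ratio, dtype=float), 0.0, 1.0)
    return t_fac * m_fac


def _decay_fraction(pool: str, abiotic, params: CarbonParams):
    """Monthly fractional loss 1 - exp(-k a); standing dead ignores abiotic."""
    k = params.monthly_rate(pool)
    if pool == "standing_dead_wood":
        return 1.0 - np.exp(-k) * np.ones_like(np.asarray(abiotic, dtype=float))
    return 1.0 - np.exp(-k * np.asarray(abiotic, dtype=float))


def step_decomposition(state: CarbonPoolState, abiotic, params: CarbonParams):
    """One month of first-order decay over all dead pools.

    Losses are evaluated simultaneously on the incoming state (analytic
    exponential decay, so pools can never go negative), then respired shares
    accumulate into Rh and transfer shares into the downstream pools.
    """
    new = state.copy()
    losses = {}
    for pool in DEAD_POOLS:
        losses[pool] = state.arrays[pool] * _decay_fraction(pool, abiotic, params)
    rh = np.zeros_like(np.asarray(abiotic, dtype=float) * state.arrays[DEAD_POOLS[0]])
    for pool in DEAD_POOLS:
        resp, targets = params.transfers[pool]
        new.arrays[pool] = new.arrays[pool] - losses[pool]
        rh = rh + resp * losses[pool]
        for target, frac in targets.items():
            new.arrays[target] = new.arrays[target] + frac * losses[pool]
    return new, rh


def step_month_carbon(state: CarbonPoolState, npp, cover_values, abiotic, params: CarbonParams):
    """Allocation, litterfall, then decomposition for one month.

    Returns ``(new_state, rh)``; the caller forms NEP = NPP - Rh.
    """
    new = state.copy()
    d_leaf, d_root, d_wood = allocate_npp(npp, cover_values, params)
    new.live_leaf = new.live_leaf + d_leaf
    new.live_root = new.live_root + d_root
    new.live_wood = new.live_wood + d_wood
    _apply_litterfall(new, litterfall(new, params), params)
    return step_decomposition(new, abiotic, params)


def net_ecosystem_production(npp: np.ndarray, rh: np.ndarray) -> np.ndarray:
    """NEP = NPP - Rh; positive = sink, negative = source."""
    npp = np.asarray(npp)
    rh = np.asarray(rh)
    if npp.shape != rh.shape:
        raise ValueError("NPP and Rh series have mismatched shapes")
    return npp - rh


def aboveground_npp(total_npp, cover_code: int, factor: float = 0.45):
    """Aboveground share of total NPP for non-riparian herbaceous cover.

    The 0.45 conversion is calibrated for herbaceous vegetation only;
    applying it to woody classes is an error.
    """
    name = COVER_NAMES.get(int(cover_code))
    if name is None:
        raise ValueError(f"unknown land-cover code {cover_code}")
    if name not in HERBACEOUS_CLASSES:
        raise ValueError(f"aboveground conversion factor is herbaceous-only, got {name}")
    return factor * np.asarray(total_npp, dtype=float)


# ---------------------------------------------------------------------------
# Linear-map view of the monthly carbon step, used by spin-up acceleration
# and by steady-state analyses.  The monthly update is the affine map
#   C' = M(a) @ L @ (C + alloc)
# where L applies litterfall transfers and M(a) the decomposition stage.


def litter_matrix(params: CarbonParams) -> np.ndarray:
    """Constant 12x12 litterfall/shedding stage matrix L."""
    n = len(POOL_NAMES)
    L = np.eye(n)
    mf = params.metabolic_fraction
    g_leaf = 1.0 / (12.0 * params.leaf_turnover_yr)
    g_root = 1.0 / (12.0 * params.root_turnover_yr)
    g_wood = 1.0 / (12.0 * params.tau_wood_yr)
    i = _IDX
    L[i["live_leaf"], i["live_leaf"]] = 1 - g_leaf
    L[i["litter_surface_metabolic"], i["live_leaf"]] = mf * g_leaf
    L[i["litter_surface_structural"], i["live_leaf"]] = (1 - mf) * g_leaf
    L[i["live_root"], i["live_root"]] = 1 - g_root
    L[i["litter_soil_metabolic"], i["live_root"]] = mf * g_root
    L[i["litter_soil_structural"], i["live_root"]] = (1 - mf) * g_root
    L[i["live_wood"], i["live_wood"]] = 1 - g_wood
    L[i["standing_dead_wood"], i["live_wood"]] = g_wood
    return L


def decomp_matrices(abiotic: np.ndarray, params: CarbonParams) -> np.ndarray:
    """Batched (n_cells, 12, 12) decomposition stage matrices M(a)."""
    a = np.asarray(abiotic, dtype=float).ravel()
    n = len(POOL_NAMES)
    M = np.zeros((a.size, n, n))
    M[:, np.arange(n), np.arange(n)] = 1.0
    for pool in DEAD_POOLS:
        f = _decay_fraction(pool, a, params)
        j = _IDX[pool]
        M[:, j, j] = 1.0 - f
        _, targets = params.transfers[pool]
        for target, frac in targets.items():
            M[:, _IDX[target], j] += frac * f
    return M
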