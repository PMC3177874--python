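# Methods

## Scope and design

`yellowcarbon` implements a monthly, gridded ecosystem carbon balance of
the light-use-efficiency family for a cold, semi-arid, fire-shaped
subalpine landscape.  Each 250-m cell carries a land-cover class, a soil
texture/rooting-depth description, and monthly forcing (EVI, air
temperature, precipitation, solar irradiance).  The stages are strictly
layered — hydrology → stress scalars → NPP → allocation/litterfall →
decomposition — and all stochasticity lives in the synthetic-data
generator; the simulator itself is deterministic, which is what makes the
conservation and fixed-point tests sharp.

## Production

NPP = Sr · EVI · e_max · T · W per cell-month.

- `e_max = 0.55 g C MJ⁻¹` applied to the supplied irradiance.  The unit
  contract is that `Sr` is the irradiance to which this efficiency applies
  (a PAR-scale monthly total, ~60 MJ m⁻² in midwinter to ~360 MJ m⁻² in
  midsummer at this latitude); no internal shortwave→PAR conversion is
  performed.
- `Topt` is the climatological mean air temperature of the month of
  maximum EVI, clamped to [0, 35] °C, derived once from the spin-up
  climatology and held fixed across simulation years.  Ties go to the
  earliest month.
- The temperature scalar is an asymmetric double logistic in `T − Topt`
  (cold-side rate 0.25 °C⁻¹, warm-side rate 0.3 °C⁻¹, both offset 10 °C
  from the optimum), normalized by its value at `T = Topt` and clipped to
  [0, 1].  This keeps the scalar ≥ 0.95 at the optimum for any `Topt`,
  monotone beyond ±5 °C, and ≤ 0.05 at 25 °C of cold departure.  The
  classic formulation also carries an inverted parabola in `Topt` alone;
  under at-optimum normalization that factor cancels, so it is omitted
  rather than carried inert.
- `W = 0.5 + 0.5·EET/PET`, with `W = 1` when PET = 0 (no atmospheric
  demand, e.g. frozen months).  The 0.5 floor keeps drought throttling
  production without shutting it off.
- Negative EVI (water, snow) contributes zero production: NPP is a
  fixation flux and is never negative.

## Hydrology

A bucket model with snowpack plus three soil layers: M1 surface organic
(fixed 10 mm capacity), M2 topsoil (0.3 m), M3 subsoil to the rooting
depth (0.5–2 m).  Field capacity densities are 100/125/150/175/200 mm per
meter of depth for coarse → fine texture classes.  Months below 0 °C route
precipitation to the snowpack; melt is degree-month at 40 mm °C⁻¹ month⁻¹
(a simple, conservative scheme; cells whose warmest month stays below
freezing accumulate permanent snow, which is tolerated — production there
is nil).  Rain plus melt recharges layers to capacity top-down; the
surplus leaves as drainage.  Surface runoff is not separated from deep
seepage: the runoff channel exists in the interface but is identically
zero in this scheme.  EET extraction is top-down with each layer yielding
in proportion to its relative saturation, never exceeding PET.

PET uses the classic Thornthwaite monthly formulation (temperature-based,
matching the data the model actually has) with day-length correction at a
configurable latitude (default 44.6°).  The warm-regime branch above
26.5 °C is not implemented because such monthly means cannot occur in this
climate envelope.  A Priestley–Taylor option was considered and not
implemented; the parameter `pet_method` records the choice.

Every step closes the water books exactly:
precip = EET + runoff + drainage + Δsnow + Δsoil (residual < 1e-9 mm,
asserted over thousands of random steps).

## Carbon pools and decomposition

Twelve pools: live leaf/root/wood; standing dead wood; downed CWD;
surface and soil litter × metabolic/structural; active, slow, passive SOM.

- Allocation: forests (evergreen/mixed/deciduous/wooded-grassland) put
  α = 45% of NPP into wood; shrubland 20% (woody shrubs); herbaceous
  classes none.  The non-wood remainder splits 50:50 leaf:root.
- Litterfall: linear monthly shedding at 1/turnover (leaf 2 yr, root 3 yr,
  wood τ = 50 yr → 2% yr⁻¹ into standing dead wood).  Leaf/root litter
  splits 50:50 metabolic:structural.
- Decomposition: analytic exponential decay per month,
  `loss = C·(1 − e^(−k·a))`, so pools cannot go negative.  Reference
  turnovers (abiotic scalar = 1): surface/soil metabolic 0.5 yr,
  structural 3 yr, downed CWD 40 yr, standing dead 100 yr (toppling only,
  no direct Rh, independent of the abiotic scalar), active 1.5 yr, slow
  25 yr, passive 1000 yr.
- Transfers: litter and CWD losses respire 55% and pass 45% to the active
  pool; active respires 30% and passes 70% to slow; slow respires 55%,
  returns 42% to active and leaks 3% to passive; passive losses are fully
  respired.  Each pool's respired + transferred shares sum to 1, so
  Δ(total pools) = NPP − Rh holds to machine precision by construction.
  Routing most of the slow outflux back to the active pool (rather than
  into the passive pool) keeps passive stocks at realistic magnitudes
  given the 1000-yr turnover.
- Abiotic rate scalar: `q10^((T−20)/10) · (0.25 + 0.75·m)` with q10 = 2
  and `m` the M1+M2 relative saturation; soil temperature is proxied by
  monthly air temperature (no heat-diffusion model).
- Litter-quality (lignin/N) rate modifiers are not represented; nitrogen
  cycling is out of scope.

## Spin-up

Pools start empty and the 12-month forcing climatology repeats until
grid-total |annual NEP| < 0.5% of annual NPP (a dead, zero-NPP landscape
converges trivially in one cycle).  Because NPP does not depend on the
pool state, one model year acts on the pool vector as an affine map
C′ = P·C + v; every 50 cycles the pools are jumped to the periodic steady
state solve (I − P)C = v, batched per cell over 12×12 matrices.  In
practice the criterion is met on the cycle after the first acceleration
(51 cycles on the default scene, final ratio ~1e-15 — numerical zero).
The criterion is enforced grid-total; the per-cell worst offenders are
reported when convergence fails.

## Observed-CWD fusion

Observed downed CWD (t biomass ha⁻¹, carbon fraction 0.5 → 100 g biomass
m⁻² per t ha⁻¹) replaces the model's downed pool where the observation has
data; the standing pool is backed out of the standing share of total dead
wood.  Injection deliberately breaks carbon conservation at that instant —
it is the disturbance discontinuity — and the run audit treats the
injected state as the opening stock, after which the books close again.

The `cwd_ratio_map` reports **default/observed** downed CWD (the figure
convention); published under-prediction factors of 2–4× are the
reciprocal reading (observed/default).  On the synthetic scene the spun-up
"default" pools are *old-growth equilibrium* stocks (inputs × effective
residence, large in a cold climate), so the ratio sits well above 1 there:
a steady-state spin-up cannot know a cell's disturbance history, which is
exactly why observed debris maps are injected in post-fire accounting.

`regrowth_time_map` divides the dead-wood stock by the annual stem-wood
increment (50% of annual NPP by default) — scale-invariant, nodata where
NPP ≤ 0 ("non-recovering").  Total CWD defaults to downed + standing.
Map legend classes break at 50 and 200 years.

## Synthetic landscape and forcing

The generator emulates the structure of the real input stack, not its
radiative-transfer detail:

- Cover and texture mosaics: smoothed Gaussian random fields thresholded
  at the configured area quantiles (default mix ≈ 43.5% evergreen forest,
  39.5% shrubland, 13% grassland, 3% water, plus minor classes), so
  classes are spatially clustered and realized fractions match the request
  to rounding.  One `SeedSequence` drives all sub-streams.
- Elevation: smoothed field spanning 1600–3000 m (inside the park's
  1540–3760 m range).  Temperature follows a sinusoid through January
  (−11.4 °C) and July (10.8 °C) normals at the 2000-m reference, lapsed at
  −6.5 °C km⁻¹, with ±1 °C year-month anomalies.  Precipitation spreads
  56.3 cm yr⁻¹ over a mild late-spring peak with 15% lognormal interannual
  CV and a 20% km⁻¹ orographic enhancement.
- EVI: per-class seasonal envelopes (evergreen keeps a 0.15 winter floor
  and peaks near 0.42; grassland/shrubland near zero in winter), a July
  greenness maximum, amplitude damped 25% km⁻¹ above 2000 m, smooth
  spatial noise (±0.04), all clamped to [−0.2, 1].  Forested cells inside
  burn perimeters are suppressed by a factor 0.65, standing in for
  regrowing sapling stands.
- Irradiance: a smooth seasonal curve (60–360 MJ m⁻² month⁻¹) uniform
  across the grid; topographic and cloud radiative effects are omitted.
- Burn perimeters: irregular star-convex polygons centered on forest,
  sized to burn ~25% of the forested area; CWD inside them draws from a
  two-regime mixture straddling 60 t ha⁻¹ (low ~35, high ~95) with a
  Beta-distributed standing fraction in [0, 0.8].

What the generator does **not** emulate — cloud/QA artifacts, spatially
correlated weather anomalies, disturbance-age mosaics, realistic dead-wood
stocks outside the mapped burns — bounds what passing tests show about
real data: they certify the numerics, conservation laws, and qualitative
climate responses of the model, not site-level predictive skill.

## Numerical choices and problem sizes

Grids are row-major from the NW corner, months 0-based from January; cell
area is cell_size² (flat geometry; no projection handling, and any
internally aligned grid is accepted).  Majority aggregation breaks ties to
the lowest class code and keeps all-nodata blocks nodata; because a block
with any valid cell yields a valid coarse cell, aggregation can enlarge
the mapped area — the cost of refusing to fabricate nodata over partial
blocks.  Zonal standard deviations are sample (n−1); polygon zones
rasterize by cell-center inclusion.  GeoTIFF I/O is handled through
`tifffile` with explicit pixel-scale/tiepoint/nodata tags (integer grids
round-trip bit-exactly, floats to ≤1e-6 relative); fire perimeters travel
as GeoJSON.

The default scene is 100×100 cells at 250 m with 7 forcing years — large
enough for stable class statistics, small enough that spin-up plus the
full simulation completes in a few seconds; the test suite uses 40×40
scenes for the slower orchestration checks.  Statistical generator
targets (class fractions ±3 pp, climate normals ±1.5 °C) are asserted at
200×200 or on multi-transect averages to keep sampling noise below the
tested effect.

## Known limitations

- Rh responds to air temperature, not modeled soil temperature; winter
  decomposition under snow is likely under-represented.
- Equilibrium dead-wood stocks in cold cells are large (effective CWD
  residence ≈ 40 yr / abiotic scalar), which is physically defensible only
  where stands are genuinely old-growth; this is the motivation for the
  observed-CWD injection pathway.
- The moisture scalar floor (0.5) and the Thornthwaite PET make the model
  mild on drought compared to energy-balance formulations.
- No nitrogen limitation, no sub-monthly dynamics, no lateral water
  routing, no within-simulation fire combustion (disturbance enters only
  through the CWD maps).
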