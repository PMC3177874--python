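#!/usr/bin/env python
"""Generate the synthetic study landscape and its 7-year forcing record.

Builds the default 100x100-cell (250 m) scene — clustered land-cover mosaic,
soil texture/rooting-depth maps, elevation, three burn perimeters, monthly
EVI/temperature/precipitation/irradiance for 2000-2006 and the post-fire
CWD maps — and writes everything under results/scene/.
"""

import os

import numpy as np

import yellowcarbon as yc
from yellowcarbon.rasters_io import COVER_NAMES
from yellowcarbon.synthetic_data import write_forcing

SEED = 1
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "scene")


def main() -> None:
    landscape, forcing, (cwd_downed, cwd_sf) = yc.default_scene(seed=SEED)
    cover, soil, elevation, fires = landscape

    os.makedirs(OUT, exist_ok=True)
    yc.write_raster(cover.grid, os.path.join(OUT, "landcover.tif"))
    yc.write_raster(soil.texture, os.path.join(OUT, "soil_texture.tif"))
    yc.write_raster(soil.rooting_depth_m, os.path.join(OUT, "rooting_depth.tif"))
    yc.write_raster(elevation, os.path.join(OUT, "elevation.tif"))
    yc.write_raster(cwd_downed, os.path.join(OUT, "cwd_downed_t_ha.tif"))
    yc.write_raster(cwd_sf, os.path.join(OUT, "cwd_standing_fraction.tif"))
    from yellowcarbon.rasters_io import write_fire_perimeters

    write_fire_perimeters(fires, os.path.join(OUT, "fires.geojson"))
    write_forcing(forcing, OUT)

    print(f"scene written to {OUT}")
    vals, counts = np.unique(cover.values, return_counts=True)
    for v, c in zip(vals, counts):
        print(f"  {COVER_NAMES[int(v)]:>18s}: {c / counts.sum():6.1%}")
    print(f"  elevation range: {elevation.values.min():.0f}-{elevation.values.max():.0f} m")
    burned = cwd_downed.values > 0
    print(f"  burned-forest cells with CWD: {burned.sum()} "
          f"(mean downed {cwd_downed.values[burned].mean():.1f} t/ha, "
          f"{(cwd_downed.values[burned] >= 60).mean():.0%} in the >=60 t/ha regime)")


if __name__ == "__main__":
    main()
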