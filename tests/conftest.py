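import numpy as np
import pytest

import yellowcarbon as yc


@pytest.fixture(scope="session")
def default_scene():
    """The default 100x100, 7-year synthetic scene (seed 1)."""
    return yc.default_scene(seed=1)


@pytest.fixture(scope="session")
def small_scene():
    """A 40x40, 2-year scene for fast spin-up/simulation tests."""
    cfg = yc.LandscapeConfig(n_rows=40, n_cols=40, seed=7)
    return yc.default_scene(seed=7, years=range(2000, 2002), cfg=cfg)


@pytest.fixture(scope="session")
def small_run(small_scene):
    """Spin-up plus full simulation of the small scene."""
    (cover, soil, elev, fires), forcing, cwd = small_scene
    sim = yc.Simulator(cover, soil)
    spin = sim.spin_up(forcing.climatology())
    result = sim.run_simulation(forcing, spin.pools, spin.water)
    return sim, spin, result


@pytest.fixture(scope="session")
def default_run(default_scene):
    """Spin-up plus 7-year simulation of the default scene."""
    (cover, soil, elev, fires), forcing, cwd = default_scene
    sim = yc.Simulator(cover, soil)
    spin = sim.spin_up(forcing.climatology())
    result = sim.run_simulation(forcing, spin.pools, spin.water)
    return sim, spin, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, **kw):
    return yc.RasterGrid(np.asarray(values), **kw)
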