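"""Thornthwaite PET and the three-layer bucket water balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yellowcarbon.hydrology import (
    HydroParams,
    SoilMoistureState,
    heat_index,
    layer_capacities,
    potential_et,
    step_water_balance,
)


def _mass_balance_residual(before, after, precip, eet, runoff, drainage):
    stored_before = before.snowpack + before.total_soil_water()
    stored_after = after.snowpack + after.total_soil_water()
    return precip + stored_before - (eet + runoff + drainage + stored_after)


class TestPotentialEt:
    def test_frozen_month_is_zero(self):
        t12 = np.array([[-12, -8, -3, 2, 7, 11, 15, 14, 9, 3, -4, -10]], dtype=float).T
        assert potential_et(-5.0, 45.0, 0, heat_index(t12)) == 0.0

    def test_matches_textbook_hand_evaluation(self):
        # Independent hand evaluation of the classic monthly formulation for a
        # 45N July with a stated 12-month temperature series.
        t12 = np.array([-10.0, -7.0, -2.0, 3.0, 8.0, 12.0, 10.0, 9.0, 5.0, 1.0, -5.0, -9.0])
        i_heat = sum((max(t, 0.0) / 5.0) ** 1.514 for t in t12)
        a = 6.75e-7 * i_heat**3 - 7.71e-5 * i_heat**2 + 1.792e-2 * i_heat + 0.49239
        pet_unadj = 16.0 * (10.0 * 10.0 / i_heat) ** a
        decl = 0.409 * math.sin(2 * math.pi * (196 - 81) / 365.0)
        omega = math.acos(-math.tan(math.radians(45.0)) * math.tan(decl))
        daylight = 24.0 / math.pi * omega
        expect = pet_unadj * daylight / 12.0 * 31.0 / 30.0
        got = potential_et(10.0, 45.0, 6, heat_index(t12.reshape(12, 1)))[0]
        assert got == pytest.approx(expect, rel=1e-12)

    def test_strictly_increasing_in_temperature(self):
        t12 = np.linspace(-10, 15, 12)
        i = heat_index(t12.reshape(12, 1))
        temps = np.linspace(1.0, 30.0, 30)
        pets = [float(potential_et(t, 45.0, 6, i)[0]) for t in temps]
        assert all(b > a for a, b in zip(pets, pets[1:]))

    def test_latitude_bounds(self):
        with pytest.raises(ValueError):
            potential_et(10.0, 95.0, 6, np.array([20.0]))


class TestWaterBalanceStep:
    caps = (np.array([10.0]), np.array([45.0]), np.array([150.0]))
    params = HydroParams()

    def _state(self, snow=0.0, m1=0.0, m2=0.0, m3=0.0):
        return SoilMoistureState(*(np.array([v], dtype=float) for v in (snow, m1, m2, m3)))

    def test_null_forcing_is_identity(self):
        s = self._state(snow=5.0, m1=3.0, m2=20.0, m3=80.0)
        new, eet, runoff, drainage = step_water_balance(
            s, 0.0, 10.0, 0.0, self.params, self.caps
        )
        # melt_coeff * 10 degC exceeds the 5 mm pack: it all melts into soil
        assert new.snowpack[0] == 0.0
        assert eet[0] == 0.0 and runoff[0] == 0.0 and drainage[0] == 0.0
        assert new.total_soil_water()[0] == pytest.approx(108.0)

    def test_null_forcing_no_snow_unchanged(self):
        s = self._state(m1=3.0, m2=20.0, m3=80.0)
        new, eet, runoff, drainage = step_water_balance(s, 0.0, 10.0, 0.0, self.params, self.caps)
        assert new.m1[0] == 3.0 and new.m2[0] == 20.0 and new.m3[0] == 80.0
        assert eet[0] == runoff[0] == drainage[0] == 0.0

    def test_saturated_profile_sheds_all_rain(self):
        s = self._state(m1=10.0, m2=45.0, m3=150.0)
        _, eet, runoff, drainage = step_water_balance(s, 100.0, 10.0, 0.0, self.params, self.caps)
        assert runoff[0] + drainage[0] == pytest.approx(100.0)
        assert eet[0] == 0.0

    def test_subzero_routes_precip_to_snowpack(self):
        s = self._state()
        new, eet, _, drainage = step_water_balance(s, 40.0, -8.0, 0.0, self.params, self.caps)
        assert new.snowpack[0] == 40.0
        assert new.total_soil_water()[0] == 0.0 and drainage[0] == 0.0

    def test_degree_month_melt_is_capped_by_pack(self):
        s = self._state(snow=30.0)
        new, *_ = step_water_balance(s, 0.0, 0.5, 0.0, self.params, self.caps)
        assert new.snowpack[0] == pytest.approx(10.0)  # 40 mm/degC * 0.5 degC melted
        s = self._state(snow=30.0)
        new, *_ = step_water_balance(s, 0.0, 5.0, 0.0, self.params, self.caps)
        assert new.snowpack[0] == 0.0  # 200 mm potential melt > 30 mm pack

    def test_eet_never_exceeds_pet_and_layers_capacity(self, rng):
        state = SoilMoistureState.zeros((500,))
        caps = (np.full(500, 10.0), rng.uniform(20, 60, 500), rng.uniform(50, 300, 500))
        for _ in range(24):
            precip = rng.gamma(2.0, 25.0, 500)
            t = rng.uniform(-15, 25, 500)
            pet = np.where(t > 0, rng.uniform(0, 120, 500), 0.0)
            state, eet, runoff, drainage = step_water_balance(
                state, precip, t, pet, self.params, caps
            )
            assert (eet <= pet + 1e-9).all()
            for layer, cap in zip((state.m1, state.m2, state.m3), caps):
                assert (layer <= cap + 1e-9).all()
                assert (layer >= 0).all()

    def test_mass_balance_closes_over_many_random_steps(self, rng):
        # ~10,000 random monthly steps: 500 cells x 20 months
        state = SoilMoistureState.zeros((500,))
        caps = (np.full(500, 10.0), rng.uniform(20, 60, 500), rng.uniform(50, 300, 500))
        for _ in range(20):
            precip = rng.gamma(2.0, 30.0, 500)
            t = rng.uniform(-15, 25, 500)
            pet = np.where(t > 0, rng.uniform(0, 120, 500), 0.0)
            before = state.copy()
            state, eet, runoff, drainage = step_water_balance(
                state, precip, t, pet, self.params, caps
            )
            residual = _mass_balance_residual(before, state, precip, eet, runoff, drainage)
            assert np.abs(residual).max() < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        precip=st.floats(0, 300), t=st.floats(-30, 30), pet=st.floats(0, 200),
        m2=st.floats(0, 45), m3=st.floats(0, 150), snow=st.floats(0, 500),
    )
    def test_single_step_conservation_property(self, precip, t, pet, m2, m3, snow):
        s = self._state(snow=snow, m2=m2, m3=m3)
        before = s.copy()
        new, eet, runoff, drainage = step_water_balance(s, precip, t, pet, self.params, self.caps)
        assert abs(_mass_balance_residual(before, new, precip, eet, runoff, drainage)[0]) < 1e-9

    def test_bad_capacities_rejected(self):
        with pytest.raises(ValueError):
            step_water_balance(self._state(), 10.0, 5.0, 0.0, self.params,
                               (np.array([0.0]), np.array([45.0]), np.array([150.0])))


class TestEquilibrium:
    def test_annual_closure_under_repeating_forcing(self):
        # After spin years, annual precip = annual (EET + runoff + drainage)
        # once the snowpack cycles close.
        params = HydroParams()
        caps = (np.array([10.0]), np.array([45.0]), np.array([150.0]))
        t12 = np.array([-11.4, -9, -4, 2, 7, 10, 10.8, 10, 6, 1, -5, -10])
        p12 = np.full(12, 47.0)
        i_heat = heat_index(t12.reshape(12, 1))
        state = SoilMoistureState.zeros((1,))
        for _ in range(10):  # spin
            for m in range(12):
                pet = potential_et(t12[m], 45.0, m, i_heat)
                state, *_ = step_water_balance(state, p12[m], t12[m], pet, params, caps)
        total_out = 0.0
        start = state.copy()
        for m in range(12):
            pet = potential_et(t12[m], 45.0, m, i_heat)
            state, eet, runoff, drainage = step_water_balance(
                state, p12[m], t12[m], pet, params, caps
            )
            total_out += float(eet[0] + runoff[0] + drainage[0])
        # cycle closes: storage returns to its start-of-year value
        assert state.snowpack[0] == pytest.approx(start.snowpack[0], abs=1e-6)
        assert total_out == pytest.approx(float(p12.sum()), rel=1e-6)

    def test_capacity_ordering_enforced(self):
        with pytest.raises(ValueError, match="increase"):
            HydroParams(field_capacity_mm_per_m={
                "coarse": 200.0, "medium_coarse": 125.0, "medium": 150.0,
                "medium_fine": 175.0, "fine": 100.0,
            })

    def test_layer_capacities_from_soil_map(self, small_scene):
        (cover, soil, *_), _, _ = small_scene
        cap1, cap2, cap3 = layer_capacities(soil)
        assert (cap1 == 10.0).all()
        assert (cap2 > 0).all() and (cap3 >= 0).all()
        # finer texture holds more water per meter
        fine = soil.texture.values == 4
        coarse = soil.texture.values == 0
        if fine.any() and coarse.any():
            assert cap2[fine].mean() > cap2[coarse].mean()
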