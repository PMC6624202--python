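"""Coupled column stepping: snow, surface boundary, conduction, hydrology."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

import cryoarch as ca
from cryoarch import soil
from cryoarch.thermal import (
    ColumnState,
    SimulationOptions,
    SnowState,
    initial_state,
    simulate,
    step_heat,
    step_snow,
    step_water,
    surface_temperature,
)


def uniform_mineral_profile(n=64, total=5.0):
    """Homogeneous column for analytic conduction checks."""
    dz = total / n
    layers = tuple(
        soil.SoilLayer(
            top_depth=i * dz, thickness=dz, porosity=0.40, loi=0.02,
            bulk_density=1500.0, hydraulic=soil.MINERAL_HYDRAULIC,
            thermal=soil.MINERAL_THERMAL,
        )
        for i in range(n)
    )
    return soil.SoilProfile(layers)


def constant_forcing(air, precip, start="2014-01-01", years=6):
    dates = pd.date_range(start, periods=int(365.25 * years), freq="D")
    return pd.DataFrame(
        {"date": dates, "air_temp_c": air, "precip_mm": precip}
    )


class TestSurfaceTemperature:
    def test_snow_free_identity(self):
        t = surface_temperature(-10.0, SnowState(swe=0.0), 0.5, 0.05, -2.0)
        assert t == -10.0

    def test_deep_snow_full_insulation(self):
        t = surface_temperature(
            -20.0, SnowState(swe=5000.0, density=300.0), 0.5, 0.05, -1.0
        )
        assert t == pytest.approx(-1.0, abs=0.05)

    def test_equal_conductance_midpoint(self):
        rho = 200.0
        k_snow = 0.021 + 2.5 * (rho / 1000.0) ** 2
        k_soil, d_soil = 0.5, 0.05
        d_snow = k_snow / (k_soil / d_soil)
        swe = d_snow * rho  # mm w.e.
        t = surface_temperature(
            -10.0, SnowState(swe=swe, density=rho), k_soil, d_soil, -2.0
        )
        assert t == pytest.approx((-10.0 - 2.0) / 2)


class TestStepSnow:
    def test_snowfall_below_threshold(self):
        # precip is snow below 0.5 degC; degree-day melt still acts above 0
        state, rain, melt = step_snow(SnowState(swe=0.0), 0.4, 5.0)
        assert rain == 0.0
        assert state.swe == pytest.approx(5.0 - melt)
        assert melt == pytest.approx(3.0 * 0.4)

    def test_rain_above_threshold(self):
        state, rain, melt = step_snow(SnowState(swe=0.0), 0.6, 5.0)
        assert state.swe == 0.0
        assert rain == pytest.approx(5.0)

    def test_melt_capped_at_swe(self):
        state, rain, melt = step_snow(SnowState(swe=10.0), 10.0, 0.0)
        assert melt == pytest.approx(10.0)  # 3 mm/degC/d would give 30
        assert state.swe == 0.0

    def test_density_compacts_toward_settled(self):
        state = SnowState(swe=100.0, density=150.0)
        for _ in range(300):
            state, _, _ = step_snow(state, -5.0, 0.0)
        assert state.density == pytest.approx(350.0, abs=5.0)


class TestStepHeat:
    def test_equilibrium_unchanged(self, default_profile):
        state = initial_state(default_profile, 5.0)
        before = state.temps.copy()
        step_heat(state, default_profile, t_surf=5.0)
        assert np.allclose(state.temps, before, atol=1e-9)

    def test_semi_infinite_step_change_matches_erf_profile(self):
        profile = uniform_mineral_profile()
        n = profile.n_layers
        state = ColumnState(
            temps=np.full(n, 5.0), liquid=np.full(n, 0.2), ice=np.zeros(n)
        )
        for _ in range(30):
            step_heat(state, profile, t_surf=15.0)
        kh = 0.70 + 1.8 * 0.2
        hc = 0.6 * 2.0e6 + 0.2 * 4.18e6
        kappa = kh / hc
        t_sec = 30 * 86400.0
        centers = np.array([l.center_depth for l in profile.layers])
        expected = 15.0 - 10.0 * erf(centers / (2 * np.sqrt(kappa * t_sec)))
        check = centers <= 2.0
        assert np.allclose(state.temps[check], expected[check], atol=0.1)

    def test_energy_conservation_through_freezing(self, default_profile):
        state = initial_state(default_profile, 2.0)
        for day in range(15):
            diag = step_heat(state, default_profile, t_surf=-10.0)
            assert diag["residual_j"] <= 1e-3 * max(diag["turnover_j"], 1.0)
        assert state.ice[0] > 0.0  # surface froze

    def test_phase_partition_consistency(self, default_profile):
        state = initial_state(default_profile, 3.0)
        for t_surf in (-15.0, -5.0, 2.0, 8.0, -3.0):
            step_heat(state, default_profile, t_surf=t_surf)
            frozen = state.ice > 0
            assert np.all(state.temps[frozen] <= 0.0)
            phi = default_profile.array("porosity")
            assert np.all(state.liquid + state.ice <= phi + 1e-9)


class TestStepWater:
    def test_saturated_over_frozen_sheds_all_rain(self, default_profile):
        n = default_profile.n_layers
        phi = default_profile.array("porosity")
        temps = np.full(n, -1.0)
        temps[0] = 1.0
        liquid = phi.copy() * 0.0
        ice = phi * 0.9
        liquid[0], ice[0] = phi[0], 0.0  # saturated unfrozen top layer
        state = ColumnState(temps=temps, liquid=liquid, ice=ice)
        before = (state.liquid * default_profile.array("thickness")).sum()
        budget = step_water(state, default_profile, rain_plus_melt_mm=10.0,
                            doy=20)
        after = (state.liquid * default_profile.array("thickness")).sum()
        assert budget["runoff_mm"] == pytest.approx(10.0, abs=1e-9)
        # storage only changes by the (dormant-season) evapotranspiration
        assert before - after == pytest.approx(
            budget["et_mm"] / 1000.0, abs=1e-12
        )

    def test_growing_season_drawdown_bounded_by_potential(
        self, default_profile
    ):
        state = initial_state(default_profile, 5.0)
        dz = default_profile.array("thickness")
        for day in range(20):
            before = (state.liquid * dz).sum() * 1000.0
            budget = step_water(state, default_profile, 0.0, doy=180)
            after = (state.liquid * dz).sum() * 1000.0
            assert before - after <= 4.0 + budget["drainage_mm"] + 1e-9
            assert budget["et_mm"] <= 4.0 + 1e-12

    def test_water_balance_closure(self, default_profile, rng):
        state = initial_state(default_profile, 5.0)
        for day in range(60):
            rain = float(rng.exponential(3.0)) if rng.random() < 0.4 else 0.0
            budget = step_water(
                state, default_profile, rain, doy=int(rng.integers(1, 366))
            )
            assert abs(budget["residual_mm"]) < 1e-6

    def test_no_liquid_flow_into_frozen_layers(self, default_profile):
        n = default_profile.n_layers
        phi = default_profile.array("porosity")
        temps = np.full(n, 5.0)
        temps[3:] = -2.0
        liquid = np.full(n, 0.1)
        ice = np.where(temps < 0, 0.2, 0.0)
        frozen_before = liquid[3:].copy()
        state = ColumnState(temps=temps, liquid=liquid.copy(), ice=ice)
        step_water(state, default_profile, 20.0, doy=200)
        assert np.allclose(state.liquid[3:], frozen_before)


class TestSimulate:
    def test_constant_forcing_steady_state(self, default_profile):
        forcing = constant_forcing(5.0, 0.0, years=6)
        res = simulate(default_profile, forcing)
        assert np.allclose(res.temp[-1], 5.0, atol=0.01)

    def test_determinism(self, default_profile):
        site = ca.DEFAULT_PRESETS[1]
        f = ca.generate_forcing(site, 2014, 2019, seed=5)
        r1 = simulate(default_profile, f)
        r2 = simulate(default_profile, f)
        assert np.array_equal(r1.temp, r2.temp)
        assert np.array_equal(r1.oc, r2.oc)

    def test_requires_post_spinup_years(self, default_profile):
        forcing = constant_forcing(5.0, 0.0, years=3)
        with pytest.raises(ValueError):
            simulate(default_profile, forcing)

    def test_spinup_years_trimmed(self, default_profile):
        site = ca.DEFAULT_PRESETS[1]
        f = ca.generate_forcing(site, 2014, 2019, seed=5)
        res = simulate(default_profile, f)
        assert res.dates[0] == pd.Timestamp("2017-01-01")
        assert res.dates[-1] == pd.Timestamp("2019-12-31")

    def test_snow_insulation_warms_winter_soil(self, default_profile):
        site = ca.DEFAULT_PRESETS[0]
        f = ca.generate_forcing(site, 2014, 2019, seed=2)
        with_snow = simulate(default_profile, f)
        without = simulate(
            default_profile, f, options=SimulationOptions(snow_enabled=False),
            init_temp=0.5,
        )
        t_with = with_snow.temp_at(0.1)
        t_without = without.temp_at(0.1)
        for year in (2017, 2018, 2019):
            wmin = t_with[t_with.index.year == year].min()
            cmin = t_without[t_without.index.year == year].min()
            assert wmin > cmin

    def test_warming_scenario_raises_soil_temperature(self, default_profile):
        site = ca.DEFAULT_PRESETS[2]
        f = ca.generate_forcing(site, 2030, 2040, seed=4)
        base = simulate(default_profile, f)
        warm = simulate(default_profile, ca.apply_scenario(f, "RCP8.5"))
        t0 = base.temp_at(0.4)
        t1 = warm.temp_at(0.4)
        assert t1.mean() > t0.mean()
        assert ca.tdd(t1).mean() >= ca.tdd(t0).mean()

    def test_inland_soil_tdd_exceeds_coastal_every_year(
        self, default_profile
    ):
        coast, inland = ca.DEFAULT_PRESETS[0], ca.DEFAULT_PRESETS[-1]
        for seed in range(1, 11):
            rc = simulate(
                default_profile,
                ca.generate_forcing(coast, 2014, 2019, seed=seed),
            )
            ri = simulate(
                default_profile,
                ca.generate_forcing(inland, 2014, 2019, seed=seed),
            )
            tdd_c = ca.tdd(rc.temp_at(0.1))
            tdd_i = ca.tdd(ri.temp_at(0.1))
            assert (tdd_i.to_numpy() > tdd_c.to_numpy()).all()

    def test_budget_diagnostics_within_tolerances(self, default_profile):
        site = ca.DEFAULT_PRESETS[2]
        f = ca.generate_forcing(site, 2014, 2018, seed=9)
        res = simulate(default_profile, f)
        rel = res.energy_residual / np.maximum(res.energy_turnover, 1.0)
        assert np.nanmax(rel) <= 1e-3
        assert np.abs(res.water_residual).max() <= 1e-6

    def test_result_csv_round_trip(self, default_profile, tmp_path):
        forcing = constant_forcing(5.0, 1.0, years=4)
        res = simulate(default_profile, forcing)
        path = tmp_path / "run.csv"
        res.write_csv(path, depths=[0.4])
        back = pd.read_csv(path, parse_dates=["date"])
        i = res.layer_index_at(0.4)
        assert np.allclose(back["temp_c"], res.temp[:, i])
        assert np.allclose(back["oc_slow"], res.oc[:, 1, i])
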