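"""Synthetic forcing generator: annual cycle, noise, precipitation, scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cryoarch import forcing as fc


def _params(**kw):
    base = dict(
        name="test",
        mean_annual_airtemp=-1.0,
        seasonal_amplitude=10.0,
        daily_noise_sd=0.0,
        annual_precip=600.0,
        summer_precip_fraction=0.4,
        continentality_index=0.5,
    )
    base.update(kw)
    return fc.SiteClimateParams(**base)


class TestGenerateForcing:
    def test_noiseless_sinusoid_extremes(self):
        df = fc.generate_forcing(_params(), 2015, 2015, seed=1)
        t = df["air_temp_c"]
        assert t.max() == pytest.approx(-1.0 + 10.0, abs=0.01)
        assert t.min() == pytest.approx(-1.0 - 10.0, abs=0.01)
        # minimum in late January, maximum in late July
        dates = pd.DatetimeIndex(df["date"])
        assert dates[t.idxmin()].month == 1
        assert dates[t.idxmax()].month in (7, 8)

    def test_mean_approaches_maat_without_noise(self):
        df = fc.generate_forcing(_params(), 2015, 2018, seed=1)
        assert df["air_temp_c"].mean() == pytest.approx(-1.0, abs=0.05)

    def test_same_seed_bit_identical(self):
        p = _params(daily_noise_sd=2.5)
        a = fc.generate_forcing(p, 2015, 2020, seed=7)
        b = fc.generate_forcing(p, 2015, 2020, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = fc.generate_forcing(p, 2015, 2020, seed=8)
        assert not np.array_equal(a["air_temp_c"], c["air_temp_c"])

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            _params(seasonal_amplitude=-1.0)
        with pytest.raises(ValueError):
            _params(summer_precip_fraction=1.5)
        with pytest.raises(ValueError):
            fc.generate_forcing(_params(), 2020, 2015, seed=1)

    def test_noise_marginal_sd(self):
        p = _params(daily_noise_sd=2.5)
        df = fc.generate_forcing(p, 2000, 2030, seed=3)
        resid = df["air_temp_c"] - fc.generate_forcing(
            _params(daily_noise_sd=0.0), 2000, 2030, seed=3
        )["air_temp_c"]
        assert resid.std() == pytest.approx(2.5, rel=0.1)
        assert resid.autocorr(1) == pytest.approx(0.7, abs=0.05)

    def test_precipitation_totals_and_summer_share(self):
        p = _params(daily_noise_sd=2.5, annual_precip=600.0,
                    summer_precip_fraction=0.4)
        totals, summer = [], []
        for seed in range(1, 11):
            df = fc.generate_forcing(p, 2015, 2018, seed=seed)
            dates = pd.DatetimeIndex(df["date"])
            years = dates.year
            for y in np.unique(years):
                m = years == y
                totals.append(df.loc[m, "precip_mm"].sum())
                sm = m & dates.month.isin([6, 7, 8])
                summer.append(df.loc[sm, "precip_mm"].sum())
        assert np.mean(totals) == pytest.approx(600.0, rel=0.10)
        assert np.mean(summer) / np.mean(totals) == pytest.approx(0.4, abs=0.05)

    def test_inland_tdd_roughly_twice_coastal(self):
        coast = fc.DEFAULT_PRESETS[0]
        inland = fc.DEFAULT_PRESETS[-1]
        ratios = []
        for seed in range(1, 11):
            fco = fc.generate_forcing(coast, 2015, 2017, seed=seed)
            fin = fc.generate_forcing(inland, 2015, 2017, seed=seed)
            t_c = pd.Series(
                fco["air_temp_c"].to_numpy(),
                index=pd.DatetimeIndex(fco["date"]),
            )
            t_i = pd.Series(
                fin["air_temp_c"].to_numpy(),
                index=pd.DatetimeIndex(fin["date"]),
            )
            ratios.append(fc.tdd(t_i).mean() / fc.tdd(t_c).mean())
        assert all(1.6 <= r <= 2.4 for r in ratios)


class TestScenario:
    def _one_day(self, date, temp=0.0):
        return pd.DataFrame(
            {"date": [pd.Timestamp(date)], "air_temp_c": [temp],
             "precip_mm": [0.0]}
        )

    def test_rcp85_summer_delta_at_2100(self):
        out = fc.apply_scenario(self._one_day("2100-07-15"), "RCP8.5")
        assert out["air_temp_c"].iloc[0] == pytest.approx(3.9)

    def test_rcp45_winter_delta_at_2100(self):
        out = fc.apply_scenario(self._one_day("2100-01-15"), "RCP4.5")
        assert out["air_temp_c"].iloc[0] == pytest.approx(3.1)

    def test_none_scenario_unchanged(self):
        df = fc.generate_forcing(_params(daily_noise_sd=1.0), 2050, 2051, 5)
        out = fc.apply_scenario(df, "none")
        pd.testing.assert_frame_equal(df, out)

    def test_ramp_is_linear_and_clipped(self):
        mid = fc.apply_scenario(self._one_day("2058-07-15"), "RCP8.5")
        frac = (2058 - 2017) / (2100 - 2017)
        assert mid["air_temp_c"].iloc[0] == pytest.approx(3.9 * frac)
        before = fc.apply_scenario(self._one_day("2010-07-15"), "RCP8.5")
        assert before["air_temp_c"].iloc[0] == pytest.approx(0.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            fc.get_scenario("RCP6.0")

    def test_scenario_monotonicity_every_day(self):
        df = fc.generate_forcing(_params(daily_noise_sd=2.0), 2040, 2060, 11)
        t0 = fc.apply_scenario(df, "none")["air_temp_c"].to_numpy()
        t45 = fc.apply_scenario(df, "RCP4.5")["air_temp_c"].to_numpy()
        t85 = fc.apply_scenario(df, "RCP8.5")["air_temp_c"].to_numpy()
        assert (t85 >= t45).all() and (t45 >= t0).all()

    def test_precip_unchanged_by_scenario(self):
        df = fc.generate_forcing(_params(daily_noise_sd=2.0), 2040, 2060, 11)
        out = fc.apply_scenario(df, "RCP8.5")
        assert np.array_equal(df["precip_mm"], out["precip_mm"])


class TestTdd:
    def _series(self, values, start="2020-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return pd.Series(values, index=idx)

    def test_direct_sum(self):
        vals = [10.0] * 30 + [-5.0] * 335
        assert fc.tdd(self._series(vals)).iloc[0] == pytest.approx(300.0)

    def test_all_frozen_gives_zero(self):
        assert fc.tdd(self._series([-3.0] * 365)).iloc[0] == 0.0

    def test_alternating_hand_sum(self):
        vals = [2.0, -2.0] * 50
        assert fc.tdd(self._series(vals)).iloc[0] == pytest.approx(100.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-30, 30), min_size=10, max_size=400))
    def test_nonnegative_and_additive(self, values):
        s = self._series(values)
        total = fc.tdd(s).sum()
        assert total >= 0.0
        split = len(values) // 2
        parts = fc.tdd(s.iloc[:split]).sum() + fc.tdd(s.iloc[split:]).sum()
        assert parts == pytest.approx(total, rel=1e-12, abs=1e-9)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        df = fc.generate_forcing(_params(daily_noise_sd=1.5), 2015, 2016, 2)
        path = tmp_path / "forcing.csv"
        fc.write_forcing_csv(df, path)
        back = fc.read_forcing_csv(path)
        assert np.allclose(df["air_temp_c"], back["air_temp_c"])
        assert np.allclose(df["precip_mm"], back["precip_mm"])

    def test_gap_detection(self):
        df = fc.generate_forcing(_params(), 2015, 2015, 2)
        gappy = pd.concat([df.iloc[:100], df.iloc[150:]])
        with pytest.raises(ValueError):
            fc.validate_forcing(gappy)
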