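"""Synthetic daily meteorological forcing for sites on a coastal–inland gradient.

West Greenland's Nuuk region spans a strong maritime-to-continental gradient:
inland sites see roughly twice the thawing degree days (TDD) of the outer
coast and markedly less rain.  This module generates daily air temperature and
precipitation series for synthetic sites parameterised along that gradient,
applies RCP-style seasonal warming ramps to 2100, and computes TDD.

Forcing series are plain :class:`pandas.DataFrame` objects with columns
``date`` (datetime64), ``air_temp_c`` and ``precip_mm``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SiteClimateParams",
    "ClimateScenario",
    "DEFAULT_PRESETS",
    "SCENARIOS",
    "get_scenario",
    "generate_forcing",
    "apply_scenario",
    "tdd",
    "read_forcing_csv",
    "write_forcing_csv",
    "validate_forcing",
]

#: Calendar day of year of the coldest day of the sinusoidal annual cycle
#: (late January); the warmest day falls half a period later (late July).
_COLDEST_DOY = 28.0
_YEAR_LENGTH = 365.25

#: Lag-1 autocorrelation of the daily temperature noise.
_AR1_RHO = 0.7
#: Probability that any given day is a precipitation day.
_WET_DAY_PROB = 0.3


@dataclass(frozen=True)
class SiteClimateParams:
    """Climate of one synthetic site.

    ``continentality_index`` runs from 0 (outer coast: cool, wet, damped
    seasonal cycle) to 1 (inland: warmer summers, dry, ample seasonal
    amplitude).
    """

    name: str
    mean_annual_airtemp: float  # deg C
    seasonal_amplitude: float  # deg C, half peak-to-peak
    daily_noise_sd: float  # deg C
    annual_precip: float  # mm
    summer_precip_fraction: float  # share of annual precip falling Jun-Aug
    continentality_index: float  # 0 coast .. 1 inland

    def __post_init__(self) -> None:
        if self.seasonal_amplitude <= 0:
            raise ValueError("seasonal_amplitude must be > 0")
        if not 0.0 <= self.summer_precip_fraction <= 1.0:
            raise ValueError("summer_precip_fraction must be in [0, 1]")
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be >= 0")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be >= 0")


def _preset(name: str, c: float) -> SiteClimateParams:
    # Coast -> inland: MAAT -1.5 -> +0.5 degC, amplitude 9 -> 14 degC,
    # precipitation 800 -> 350 mm, summer precip share 0.35 -> 0.45.
    return SiteClimateParams(
        name=name,
        mean_annual_airtemp=-1.5 + 2.0 * c,
        seasonal_amplitude=9.0 + 5.0 * c,
        daily_noise_sd=2.5,
        annual_precip=800.0 - 450.0 * c,
        summer_precip_fraction=0.35 + 0.10 * c,
        continentality_index=c,
    )


#: Five synthetic sites spanning the coastal–inland gradient.
DEFAULT_PRESETS: tuple[SiteClimateParams, ...] = (
    _preset("outer-coast", 0.00),
    _preset("mid-coast", 0.25),
    _preset("mid-fjord", 0.50),
    _preset("inner-fjord", 0.75),
    _preset("inland", 1.00),
)


@dataclass(frozen=True)
class ClimateScenario:
    """Seasonal air-temperature deltas at 2100, ramped linearly from 2017.

    Deltas are relative to the present-day (ramp-start) climate; the ramp
    factor is ``(year - ramp_start) / (ramp_end - ramp_start)`` clipped to
    [0, 1].  Precipitation is left unchanged.
    """

    name: str
    delta_winter: float  # DJF, deg C at ramp_end_year
    delta_spring: float  # MAM
    delta_summer: float  # JJA
    delta_autumn: float  # SON
    ramp_start_year: int = 2017
    ramp_end_year: int = 2100

    def __post_init__(self) -> None:
        if self.ramp_end_year <= self.ramp_start_year:
            raise ValueError("ramp_end_year must exceed ramp_start_year")
        deltas = (self.delta_winter, self.delta_spring,
                  self.delta_summer, self.delta_autumn)
        if self.name == "none" and any(d != 0.0 for d in deltas):
            raise ValueError('scenario "none" must have all-zero deltas')
        if self.name != "none" and any(d < 0.0 for d in deltas):
            raise ValueError("RCP scenario deltas must be >= 0")

    def season_delta(self, month: int) -> float:
        if month in (12, 1, 2):
            return self.delta_winter
        if month in (3, 4, 5):
            return self.delta_spring
        if month in (6, 7, 8):
            return self.delta_summer
        return self.delta_autumn


# HIRHAM5-derived warming by 2100 relative to the 2000-2017 mean.
SCENARIOS: dict[str, ClimateScenario] = {
    "none": ClimateScenario("none", 0.0, 0.0, 0.0, 0.0),
    "RCP4.5": ClimateScenario("RCP4.5", 3.1, 2.5, 2.0, 2.5),
    "RCP8.5": ClimateScenario("RCP8.5", 6.0, 5.0, 3.9, 5.0),
}


def get_scenario(name: str) -> ClimateScenario:
    """Look up a scenario by name (``none``, ``RCP4.5`` or ``RCP8.5``)."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


def generate_forcing(
    params: SiteClimateParams,
    start_year: int,
    end_year: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a daily forcing series for ``start_year``..``end_year`` inclusive.

    Air temperature is a sinusoidal annual cycle (minimum in late January,
    maximum in late July) plus AR(1) daily noise with marginal standard
    deviation ``params.daily_noise_sd``.  Precipitation falls on random wet
    days (probability 0.3) with exponentially distributed amounts whose
    expectation reproduces ``annual_precip`` and its Jun–Aug share.

    Identical ``(params, years, seed)`` give a bit-identical series.
    """
    if start_year > end_year:
        raise ValueError("start_year must not exceed end_year")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=np.float64)
    n = len(dates)

    season = params.mean_annual_airtemp - params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - _COLDEST_DOY) / _YEAR_LENGTH
    )

    if params.daily_noise_sd > 0:
        z = rng.standard_normal(n)
        noise = np.empty(n)
        noise[0] = z[0] * params.daily_noise_sd
        innov_sd = params.daily_noise_sd * np.sqrt(1.0 - _AR1_RHO**2)
        for t in range(1, n):
            noise[t] = _AR1_RHO * noise[t - 1] + innov_sd * z[t]
    else:
        noise = np.zeros(n)

    air_temp = season + noise

    # Precipitation: Bernoulli wet days, exponential amounts; mean amount set
    # per season so annual total and its summer share are met in expectation.
    month = dates.month.to_numpy()
    is_summer = (month >= 6) & (month <= 8)
    n_summer_per_year = 92.0
    n_rest_per_year = _YEAR_LENGTH - n_summer_per_year
    mean_summer = (
        params.summer_precip_fraction * params.annual_precip
        / (_WET_DAY_PROB * n_summer_per_year)
    )
    mean_rest = (
        (1.0 - params.summer_precip_fraction) * params.annual_precip
        / (_WET_DAY_PROB * n_rest_per_year)
    )
    wet = rng.random(n) < _WET_DAY_PROB
    amounts = rng.exponential(1.0, n)
    precip = np.where(
        wet, amounts * np.where(is_summer, mean_summer, mean_rest), 0.0
    )

    return pd.DataFrame(
        {"date": dates, "air_temp_c": air_temp, "precip_mm": precip}
    )


def apply_scenario(
    forcing: pd.DataFrame, scenario: ClimateScenario | str
) -> pd.DataFrame:
    """Return a copy of ``forcing`` with the scenario warming ramp applied.

    Each day's temperature is raised by the season's 2100 delta scaled by the
    linear ramp factor for that year; precipitation is unchanged.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    out = forcing.copy()
    dates = pd.DatetimeIndex(out["date"])
    years = dates.year.to_numpy()
    months = dates.month.to_numpy()
    ramp = np.clip(
        (years - scenario.ramp_start_year)
        / (scenario.ramp_end_year - scenario.ramp_start_year),
        0.0,
        1.0,
    )
    deltas = np.array([scenario.season_delta(m) for m in range(1, 13)])
    out["air_temp_c"] = out["air_temp_c"].to_numpy() + ramp * deltas[months - 1]
    return out


def tdd(series: pd.Series) -> pd.Series:
    """Thawing degree days per calendar year.

    ``series`` is a daily temperature series with a DatetimeIndex; the result
    is indexed by year and sums the positive daily means (deg C * days).
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("tdd expects a Series with a DatetimeIndex")
    positive = series.clip(lower=0.0)
    return positive.groupby(series.index.year).sum()


def validate_forcing(forcing: pd.DataFrame) -> None:
    """Reject forcing with gaps, unsorted dates or negative precipitation."""
    dates = pd.DatetimeIndex(forcing["date"])
    if len(dates) == 0:
        raise ValueError("empty forcing")
    deltas = np.diff(dates.to_numpy().astype("datetime64[D]").astype(np.int64))
    if not np.all(deltas == 1):
        raise ValueError("forcing dates must be strictly daily with no gaps")
    if (forcing["precip_mm"].to_numpy() < 0).any():
        raise ValueError("negative precipitation in forcing")


def write_forcing_csv(forcing: pd.DataFrame, path) -> None:
    out = forcing.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_forcing_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    expected = ["date", "air_temp_c", "precip_mm"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"forcing CSV must have columns {expected}")
    validate_forcing(df)
    return df
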