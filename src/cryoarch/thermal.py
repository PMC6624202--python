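"""Coupled daily heat–water–carbon stepping of the soil column.

The column is driven by daily air temperature and precipitation.  Each day:
snow accumulates/melts (precipitation is snow below 0.5 deg C air
temperature), the surface temperature is set from the air temperature with a
snow-insulation conductance weighting, heat diffuses through the column in
hourly implicit substeps with freeze–thaw latent heat, water infiltrates and
redistributes in a bucket cascade with evapotranspiration (4 mm/day over a
140-day growing season) and conductivity-limited drainage, and the carbon
pools degrade on the daily mean state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .carbon import DAYS_PER_YEAR, CarbonPools, DegradationParams
from .forcing import validate_forcing
from .soil import SoilProfile, field_capacity, retention_inverse

__all__ = [
    "SnowState",
    "ColumnState",
    "SimulationOptions",
    "SimulationResult",
    "ConvergenceError",
    "surface_temperature",
    "step_snow",
    "step_heat",
    "step_water",
    "simulate",
    "GROWING_SEASON",
    "ET_GROWING_MM",
    "ET_DORMANT_MM",
    "ROOT_EFOLD_M",
]

#: Growing season day-of-year window (inclusive), 140 days.
GROWING_SEASON = (152, 291)
ET_GROWING_MM = 4.0  # potential evapotranspiration in season, mm/day
ET_DORMANT_MM = 0.5  # outside the season
#: Root density e-folding depth; puts 90 % of water uptake above 0.3 m.
ROOT_EFOLD_M = 0.3 / np.log(10.0)
#: Matric head at the wilting point (m); root uptake stops here.
WILTING_HEAD_M = 150.0


class ConvergenceError(RuntimeError):
    """Raised when the freeze–thaw Picard iteration fails to converge."""


@dataclass
class SnowState:
    swe: float = 0.0  # mm water equivalent
    density: float = _core.FRESH_SNOW_DENSITY  # kg m^-3

    @property
    def depth(self) -> float:
        """Snowpack depth in metres."""
        return self.swe / self.density if self.swe > 0 else 0.0


@dataclass
class ColumnState:
    """Per-layer thermal/hydrological state of the column."""

    temps: np.ndarray  # deg C
    liquid: np.ndarray  # vol fraction
    ice: np.ndarray  # vol fraction
    snow: SnowState = field(default_factory=SnowState)

    def copy(self) -> "ColumnState":
        return ColumnState(
            self.temps.copy(),
            self.liquid.copy(),
            self.ice.copy(),
            SnowState(self.snow.swe, self.snow.density),
        )


@dataclass(frozen=True)
class SimulationOptions:
    heat_feedback: bool = False
    snow_enabled: bool = True
    substeps_per_day: int = 24
    spinup_years: int = 3
    loi_to_oc: float = 0.5
    rate_scale: float = 1.0  # uniform rescaling of the three pool rates


def _profile_arrays(profile: SoilProfile) -> dict[str, np.ndarray]:
    dz = profile.array("thickness")
    tops = profile.array("top_depth")
    arr = {
        "dz": dz,
        "phi": profile.array("porosity"),
        "hc_solids": profile.array("hc_solids"),
        "kh_dry": profile.array("kh_dry"),
        "kh_slope": profile.array("kh_slope"),
        "kh_frozen_factor": profile.array("kh_frozen_factor"),
        "theta_r": profile.array("residual_water"),
        "ksat": profile.array("ksat_m_per_day"),
        "k_exp": 2.5 + 2.0 / profile.array("pore_size_index"),
        "psi_ae": profile.array("air_entry_m"),
        "bc_lambda": profile.array("pore_size_index"),
        "theta_fc": np.array(
            [field_capacity(l) for l in profile.layers], dtype=float
        ),
        "theta_wp": np.array(
            [retention_inverse(WILTING_HEAD_M, l) for l in profile.layers],
            dtype=float,
        ),
    }
    bots = tops + dz
    root = np.exp(-tops / ROOT_EFOLD_M) - np.exp(-bots / ROOT_EFOLD_M)
    arr["root_frac"] = root / root.sum()
    return arr


def estimate_mean_surface_temperature(
    profile: SoilProfile, forcing: pd.DataFrame
) -> float:
    """Mean annual ground-surface temperature implied by the snow model.

    Runs the snow and surface-temperature scheme over the first forcing
    year (ground temperature approximated as 0 deg C under snow) and
    averages the result.  Snow insulation makes this warmer than the mean
    air temperature; it is the appropriate uniform initial condition for the
    column, which otherwise starts in a spurious multi-decade permafrost
    transient wherever snow cover is substantial.
    """
    dates = pd.DatetimeIndex(forcing["date"])
    first = dates.year == dates.year[0]
    air = forcing.loc[first, "air_temp_c"].to_numpy(dtype=float)
    precip = forcing.loc[first, "precip_mm"].to_numpy(dtype=float)
    arr = _profile_arrays(profile)
    top = profile.layers[0]
    kh_top = top.thermal.kh_dry + top.thermal.kh_slope * arr["theta_fc"][0]
    swe, rho = 0.0, _core.FRESH_SNOW_DENSITY
    total = 0.0
    for i in range(air.size):
        swe, rho, _, _ = _core.snow_day(swe, rho, air[i], precip[i])
        total += _core.surface_temperature(
            air[i], swe, rho, kh_top, arr["dz"][0], 0.0
        )
    return total / air.size


def initial_state(
    profile: SoilProfile, init_temp: float
) -> ColumnState:
    """Uniform initial temperature, water at field capacity, phase-consistent."""
    n = profile.n_layers
    temps = np.full(n, float(init_temp))
    wtot = np.array([field_capacity(l) for l in profile.layers])
    fl = np.array([_core.liquid_fraction(t) for t in temps])
    return ColumnState(temps=temps, liquid=wtot * fl, ice=wtot * (1.0 - fl))


# ---------------------------------------------------------------------------
# Single-operation wrappers (shared kernels with the full simulation)
# ---------------------------------------------------------------------------

def surface_temperature(
    air_temp: float,
    snow: SnowState,
    top_layer_kh: float,
    top_layer_dz: float,
    top_layer_temp: float,
) -> float:
    """Surface boundary temperature (snow-free: the air temperature)."""
    return float(
        _core.surface_temperature(
            air_temp, snow.swe, snow.density, top_layer_kh, top_layer_dz,
            top_layer_temp,
        )
    )


def step_snow(
    state: SnowState, air_temp: float, precip_mm: float
) -> tuple[SnowState, float, float]:
    """Advance the snowpack one day; returns ``(state, rain_mm, melt_mm)``."""
    swe, rho, rain, melt = _core.snow_day(
        state.swe, state.density, air_temp, precip_mm
    )
    return SnowState(swe, rho), rain, melt


def step_heat(
    state: ColumnState,
    profile: SoilProfile,
    t_surf: float,
    n_sub: int = 24,
    source: np.ndarray | None = None,
) -> dict[str, float]:
    """One day of conduction (in place); returns energy diagnostics.

    The returned dict holds the boundary heat input ``flux_top_j``, the
    accumulated absolute energy residual ``residual_j`` and enthalpy turnover
    ``turnover_j`` over the substeps.
    """
    arr = _profile_arrays(profile)
    if source is None:
        source = np.zeros(profile.n_layers)
    wtot = state.liquid + state.ice
    flux, res, turn, flag = _core.heat_day(
        state.temps,
        wtot,
        arr["dz"],
        arr["phi"],
        arr["hc_solids"],
        arr["kh_dry"],
        arr["kh_slope"],
        arr["kh_frozen_factor"],
        float(t_surf),
        np.asarray(source, dtype=float),
        n_sub,
        200,
    )
    if flag >= 0:
        raise ConvergenceError(
            f"freeze-thaw iteration failed at substep {flag} "
            f"(t_surf={t_surf:.2f} degC)"
        )
    _core.partition_phase(state.temps, state.liquid, state.ice)
    return {"flux_top_j": flux, "residual_j": res, "turnover_j": turn}


def step_water(
    state: ColumnState,
    profile: SoilProfile,
    rain_plus_melt_mm: float,
    doy: int,
) -> dict[str, float]:
    """One day of bucket hydrology (in place); returns the water budget (mm)."""
    arr = _profile_arrays(profile)
    et_pot = (
        ET_GROWING_MM
        if GROWING_SEASON[0] <= doy <= GROWING_SEASON[1]
        else ET_DORMANT_MM
    )
    runoff, drainage, et_act, residual = _core.water_day(
        state.liquid,
        state.ice,
        state.temps,
        arr["dz"],
        arr["phi"],
        arr["theta_r"],
        arr["theta_fc"],
        arr["theta_wp"],
        arr["ksat"],
        arr["k_exp"],
        arr["psi_ae"],
        arr["bc_lambda"],
        rain_plus_melt_mm / 1000.0,
        et_pot / 1000.0,
        arr["root_frac"],
    )
    return {
        "runoff_mm": runoff * 1000.0,
        "drainage_mm": drainage * 1000.0,
        "et_mm": et_act * 1000.0,
        "residual_mm": residual * 1000.0,
    }


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Daily, per-layer output of a coupled run (spin-up years removed)."""

    dates: pd.DatetimeIndex
    profile: SoilProfile
    temp: np.ndarray  # (days, layers), deg C
    liquid: np.ndarray  # (days, layers)
    ice: np.ndarray  # (days, layers)
    oc: np.ndarray  # (days, 3, layers), kg C m^-3
    loss: np.ndarray  # (days, layers), kg C m^-3 d^-1
    swe: np.ndarray  # (days,), mm
    t_surf: np.ndarray  # (days,)
    runoff: np.ndarray  # (days,), mm
    drainage: np.ndarray  # (days,), mm
    et: np.ndarray  # (days,), mm
    energy_residual: np.ndarray  # (days,), J per day
    energy_turnover: np.ndarray  # (days,), J per day
    water_residual: np.ndarray  # (days,), mm per day
    options: SimulationOptions = field(default_factory=SimulationOptions)

    @property
    def depth_centers(self) -> np.ndarray:
        return np.array([l.center_depth for l in self.profile.layers])

    def layer_index_at(self, depth: float) -> int:
        return self.profile.layer_index_at(depth)

    def temp_at(self, depth: float) -> pd.Series:
        """Daily temperature series for the layer containing ``depth``."""
        return pd.Series(
            self.temp[:, self.layer_index_at(depth)], index=self.dates
        )

    def slow_pool_at(self, depth: float) -> pd.Series:
        return pd.Series(
            self.oc[:, 1, self.layer_index_at(depth)], index=self.dates
        )

    def to_dataframe(self, depths=None) -> pd.DataFrame:
        """Tidy long-format frame (date, depth, state) for selected depths."""
        if depths is None:
            idx = np.arange(self.profile.n_layers)
        else:
            idx = np.array([self.layer_index_at(d) for d in depths])
        frames = []
        centers = self.depth_centers
        for i in idx:
            frames.append(
                pd.DataFrame(
                    {
                        "date": self.dates,
                        "depth_m": centers[i],
                        "temp_c": self.temp[:, i],
                        "liquid_vol": self.liquid[:, i],
                        "ice_vol": self.ice[:, i],
                        "oc_fast": self.oc[:, 0, i],
                        "oc_slow": self.oc[:, 1, i],
                        "oc_passive": self.oc[:, 2, i],
                        "loss_total": self.loss[:, i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path, depths=None) -> None:
        self.to_dataframe(depths).to_csv(path, index=False)


def simulate(
    profile: SoilProfile,
    forcing: pd.DataFrame,
    params: DegradationParams | None = None,
    options: SimulationOptions | None = None,
    init_temp: float | None = None,
) -> SimulationResult:
    """Run the coupled column model over a daily forcing series.

    The first ``options.spinup_years`` calendar years of the forcing are
    simulated to settle the state and then discarded from the result; the
    forcing must therefore cover the analysis window plus spin-up.
    """
    params = params or DegradationParams()
    options = options or SimulationOptions()
    validate_forcing(forcing)

    dates = pd.DatetimeIndex(forcing["date"])
    years = dates.year.to_numpy()
    if len(np.unique(years)) <= options.spinup_years:
        raise ValueError("forcing must extend beyond the spin-up years")

    air = forcing["air_temp_c"].to_numpy(dtype=float)
    precip = forcing["precip_mm"].to_numpy(dtype=float)
    doy = dates.dayofyear.to_numpy()
    et_pot = np.where(
        (doy >= GROWING_SEASON[0]) & (doy <= GROWING_SEASON[1]),
        ET_GROWING_MM,
        ET_DORMANT_MM,
    )

    arr = _profile_arrays(profile)
    n = profile.n_layers
    n_days = len(dates)

    if init_temp is None:
        init_temp = estimate_mean_surface_temperature(profile, forcing)
    state = initial_state(profile, init_temp)

    pools = CarbonPools.from_profile(profile, params, options.loi_to_oc)
    k_day = (
        options.rate_scale
        / np.asarray(params.turnover_years, dtype=float)
        / DAYS_PER_YEAR
    )
    mr = params.moisture

    out = {
        "temp": np.empty((n_days, n)),
        "liquid": np.empty((n_days, n)),
        "ice": np.empty((n_days, n)),
        "oc": np.empty((n_days, 3, n)),
        "loss": np.empty((n_days, n)),
        "swe": np.empty(n_days),
        "t_surf": np.empty(n_days),
        "runoff": np.empty(n_days),
        "drainage": np.empty(n_days),
        "et": np.empty(n_days),
        "energy_residual": np.empty(n_days),
        "energy_turnover": np.empty(n_days),
        "water_residual": np.empty(n_days),
    }

    flag = _core.run_simulation(
        air,
        precip,
        et_pot,
        arr["dz"],
        arr["phi"],
        arr["hc_solids"],
        arr["kh_dry"],
        arr["kh_slope"],
        arr["kh_frozen_factor"],
        arr["theta_r"],
        arr["theta_fc"],
        arr["theta_wp"],
        arr["ksat"],
        arr["k_exp"],
        arr["psi_ae"],
        arr["bc_lambda"],
        arr["root_frac"],
        state.temps,
        state.liquid,
        state.ice,
        state.snow.swe,
        state.snow.density,
        pools.oc,
        k_day,
        params.q10,
        params.ref_temp,
        params.frozen_cutoff,
        mr.s_lo,
        mr.s_opt_lo,
        mr.s_opt_hi,
        mr.f_sat,
        params.heat_yield_mj_per_kg * 1e6,
        options.heat_feedback,
        options.snow_enabled,
        options.substeps_per_day,
        out["temp"],
        out["liquid"],
        out["ice"],
        out["oc"],
        out["loss"],
        out["swe"],
        out["t_surf"],
        out["runoff"],
        out["drainage"],
        out["et"],
        out["energy_residual"],
        out["energy_turnover"],
        out["water_residual"],
    )
    if flag >= 0:
        raise ConvergenceError(
            f"freeze-thaw iteration failed on {dates[flag].date()}"
        )

    # Trim spin-up calendar years.
    spinup_cutoff = years[0] + options.spinup_years
    keep = years >= spinup_cutoff
    return SimulationResult(
        dates=dates[keep],
        profile=profile,
        temp=out["temp"][keep],
        liquid=out["liquid"][keep],
        ice=out["ice"][keep],
        oc=out["oc"][keep],
        loss=out["loss"][keep],
        swe=out["swe"][keep],
        t_surf=out["t_surf"][keep],
        runoff=out["runoff"][keep],
        drainage=out["drainage"][keep],
        et=out["et"][keep],
        energy_residual=out["energy_residual"][keep],
        energy_turnover=out["energy_turnover"][keep],
        water_residual=out["water_residual"][keep],
        options=options,
    )
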