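"""Numerical kernels for the daily column step (numba-compiled).

Everything here operates on plain float64 arrays; the public API in
:mod:`cryoarch.thermal` wraps these kernels.  Heat conduction uses an
enthalpy (apparent-heat-capacity) formulation: enthalpy is piecewise linear
in temperature with the latent heat of fusion spread over the freezing
interval [-FREEZE_SPAN, 0] deg C, and each implicit substep is solved by a
semismooth Newton iteration on the enthalpy balance, which conserves energy
by construction at convergence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Physical constants
HC_WATER = 4.18e6  # J m^-3 K^-1
HC_ICE = 1.9e6  # J m^-3 K^-1
LATENT_VOL = 334.0e3 * 1000.0  # J m^-3 per unit vol fraction of water frozen
FREEZE_SPAN = 0.5  # deg C; phase change spread over [-FREEZE_SPAN, 0]

# Snow model constants
SNOW_TEMP_THRESHOLD = 0.5  # deg C; precip is snow below this air temperature
MELT_FACTOR = 3.0  # mm w.e. per deg C per day
FRESH_SNOW_DENSITY = 150.0  # kg m^-3
SETTLED_SNOW_DENSITY = 350.0  # kg m^-3
SNOW_COMPACTION_RATE = 0.02  # fraction of (settled - current) per day
MIN_SWE_MM = 0.1  # below this the ground counts as snow-free

SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 365.25


@njit(cache=True)
def liquid_fraction(temp):
    """Fraction of freezable water that is liquid at temperature ``temp``."""
    if temp >= 0.0:
        return 1.0
    if temp <= -FREEZE_SPAN:
        return 0.0
    return 1.0 + temp / FREEZE_SPAN


@njit(cache=True)
def _enthalpy(temp, cu, cf, cm, lw):
    """Volumetric enthalpy (J m^-3) relative to unfrozen soil at 0 deg C."""
    if temp >= 0.0:
        return cu * temp
    if temp >= -FREEZE_SPAN:
        return (cm + lw / FREEZE_SPAN) * temp
    return -(cm * FREEZE_SPAN + lw) + cf * (temp + FREEZE_SPAN)


@njit(cache=True)
def _enthalpy_slope(temp, cu, cf, cm, lw):
    if temp >= 0.0:
        return cu
    if temp >= -FREEZE_SPAN:
        return cm + lw / FREEZE_SPAN
    return cf


@njit(cache=True)
def _thomas(a, b, c, d):
    """Solve a tridiagonal system in place; returns the solution in d."""
    n = b.shape[0]
    for i in range(1, n):
        m = a[i] / b[i - 1]
        b[i] = b[i] - m * c[i - 1]
        d[i] = d[i] - m * d[i - 1]
    d[n - 1] = d[n - 1] / b[n - 1]
    for i in range(n - 2, -1, -1):
        d[i] = (d[i] - c[i] * d[i + 1]) / b[i]
    return d


@njit(cache=True)
def conductivity_profile(temps, wtot, kh_dry, kh_slope, kh_frozen_factor):
    """Thermal conductivity per layer, blending frozen/unfrozen with phase."""
    n = temps.shape[0]
    kh = np.empty(n)
    for i in range(n):
        fl = liquid_fraction(temps[i])
        khu = kh_dry[i] + kh_slope[i] * wtot[i]
        kh[i] = khu * (kh_frozen_factor[i] - (kh_frozen_factor[i] - 1.0) * fl)
    return kh


@njit(cache=True)
def heat_day(
    temps,
    wtot,
    dz,
    phi,
    hc_solids,
    kh_dry,
    kh_slope,
    kh_frozen_factor,
    t_surf,
    source,
    n_sub,
    max_iter,
):
    """Advance temperatures one day with ``n_sub`` implicit substeps.

    ``source`` is a volumetric heat source per layer (W m^-3).  Dirichlet
    boundary at the surface (``t_surf``), zero flux at the bottom.  Returns
    ``(flux_top_J, energy_residual_J, energy_turnover_J, iterations_flag)``
    where the flag is -1 on success or the failing substep index.
    """
    n = temps.shape[0]
    dt = SECONDS_PER_DAY / n_sub

    cu = np.empty(n)
    cf = np.empty(n)
    cm = np.empty(n)
    lw = np.empty(n)
    for i in range(n):
        solid = (1.0 - phi[i]) * hc_solids[i]
        cu[i] = solid + wtot[i] * HC_WATER
        cf[i] = solid + wtot[i] * HC_ICE
        cm[i] = 0.5 * (cu[i] + cf[i])
        lw[i] = LATENT_VOL * wtot[i]

    flux_top_total = 0.0
    residual_total = 0.0
    turnover_total = 0.0

    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    d = np.empty(n)
    g = np.empty(n - 1)

    resid = np.empty(n)
    resid_try = np.empty(n)
    t_try = np.empty(n)

    for step in range(n_sub):
        t_old = temps.copy()
        h_old = np.empty(n)
        for i in range(n):
            h_old[i] = _enthalpy(t_old[i], cu[i], cf[i], cm[i], lw[i])

        # Semismooth Newton with backtracking on the enthalpy-balance
        # residual; the piecewise-linear enthalpy makes plain Picard cycle
        # across the freezing breakpoints, Newton does not.
        t_k = temps.copy()
        converged = False
        g0 = 0.0
        for _ in range(max_iter):
            kh = conductivity_profile(
                t_k, wtot, kh_dry, kh_slope, kh_frozen_factor
            )
            for i in range(n - 1):
                g[i] = 1.0 / (
                    dz[i] / (2.0 * kh[i]) + dz[i + 1] / (2.0 * kh[i + 1])
                )
            g0 = 2.0 * kh[0] / dz[0]

            # residual of the implicit enthalpy balance, W m^-2 per layer
            rnorm = 0.0
            for i in range(n):
                resid[i] = (
                    _enthalpy(t_k[i], cu[i], cf[i], cm[i], lw[i]) - h_old[i]
                ) * dz[i] / dt - source[i] * dz[i]
            resid[0] -= g0 * (t_surf - t_k[0])
            for i in range(n - 1):
                fl = g[i] * (t_k[i + 1] - t_k[i])
                resid[i] -= fl
                resid[i + 1] += fl
            for i in range(n):
                if abs(resid[i]) > rnorm:
                    rnorm = abs(resid[i])
            if rnorm < 1e-6:
                converged = True
                break

            # Newton system: diag(H') / dt + conduction operator
            for i in range(n):
                b[i] = (
                    _enthalpy_slope(t_k[i], cu[i], cf[i], cm[i], lw[i])
                    * dz[i] / dt
                )
                a[i] = 0.0
                c[i] = 0.0
                d[i] = -resid[i]
            b[0] += g0
            for i in range(n - 1):
                b[i] += g[i]
                c[i] = -g[i]
                b[i + 1] += g[i]
                a[i + 1] = -g[i]
            dt_step = _thomas(a, b, c, d)

            # backtracking line search on the residual norm (kh lagged)
            scale = 1.0
            for _ls in range(30):
                for i in range(n):
                    t_try[i] = t_k[i] + scale * dt_step[i]
                rtry = 0.0
                for i in range(n):
                    resid_try[i] = (
                        _enthalpy(t_try[i], cu[i], cf[i], cm[i], lw[i])
                        - h_old[i]
                    ) * dz[i] / dt - source[i] * dz[i]
                resid_try[0] -= g0 * (t_surf - t_try[0])
                for i in range(n - 1):
                    fl = g[i] * (t_try[i + 1] - t_try[i])
                    resid_try[i] -= fl
                    resid_try[i + 1] += fl
                for i in range(n):
                    if abs(resid_try[i]) > rtry:
                        rtry = abs(resid_try[i])
                if rtry < rnorm or scale < 1e-4:
                    break
                scale *= 0.5
            for i in range(n):
                t_k[i] = t_try[i]
        if not converged:
            return 0.0, 0.0, 0.0, step

        for i in range(n):
            temps[i] = t_k[i]

        flux_top = g0 * (t_surf - temps[0]) * dt
        flux_top_total += flux_top
        dh_sum = 0.0
        dh_abs = 0.0
        for i in range(n):
            dh = (
                _enthalpy(temps[i], cu[i], cf[i], cm[i], lw[i]) - h_old[i]
            ) * dz[i]
            dh_sum += dh
            dh_abs += abs(dh)
        src = 0.0
        for i in range(n):
            src += source[i] * dz[i] * dt
        residual_total += abs(dh_sum - flux_top - src)
        turnover_total += dh_abs

    return flux_top_total, residual_total, turnover_total, -1


@njit(cache=True)
def partition_phase(temps, liq, ice):
    """Repartition liquid/ice consistently with temperature."""
    n = temps.shape[0]
    for i in range(n):
        w = liq[i] + ice[i]
        fl = liquid_fraction(temps[i])
        liq[i] = w * fl
        ice[i] = w * (1.0 - fl)


@njit(cache=True)
def snow_day(swe, rho, air_temp, precip_mm):
    """One day of snow accumulation, melt and compaction.

    Returns ``(swe, rho, rain_mm, melt_mm)``; precipitation below the 0.5 degC
    air-temperature threshold accumulates as snow, otherwise it is rain.
    """
    rain = 0.0
    if air_temp < SNOW_TEMP_THRESHOLD:
        if swe + precip_mm > 0.0:
            rho = (swe * rho + precip_mm * FRESH_SNOW_DENSITY) / (
                swe + precip_mm
            )
        swe += precip_mm
    else:
        rain = precip_mm
    melt = 0.0
    if air_temp > 0.0 and swe > 0.0:
        melt = MELT_FACTOR * air_temp
        if melt > swe:
            melt = swe
        swe -= melt
    rho += (SETTLED_SNOW_DENSITY - rho) * SNOW_COMPACTION_RATE
    if rho < 100.0:
        rho = 100.0
    if rho > 450.0:
        rho = 450.0
    return swe, rho, rain, melt


@njit(cache=True)
def snow_conductivity(rho):
    """Snow thermal conductivity from density (W m^-1 K^-1)."""
    return 0.021 + 2.5 * (rho / 1000.0) ** 2


@njit(cache=True)
def surface_temperature(air_temp, swe, rho, top_kh, top_dz, top_temp):
    """Surface boundary temperature; snow insulates by conductance weighting.

    Snow-free ground takes the air temperature directly.  Under snow the
    surface temperature is ``w * T_air + (1 - w) * T_top`` with ``w`` the
    snow conductance share ``(k_snow/d_snow) / (k_snow/d_snow + k_soil/d_soil)``.
    """
    if swe <= MIN_SWE_MM:
        return air_temp
    d_snow = swe / rho  # swe in mm == kg m^-2; depth in m
    cond_snow = snow_conductivity(rho) / d_snow
    cond_soil = top_kh / top_dz
    w = cond_snow / (cond_snow + cond_soil)
    return w * air_temp + (1.0 - w) * top_temp


@njit(cache=True)
def water_day(
    liq,
    ice,
    temps,
    dz,
    phi,
    theta_r,
    theta_fc,
    theta_wp,
    ksat,
    k_exp,
    psi_ae,
    bc_lambda,
    water_in_m,
    et_pot_m,
    root_frac,
):
    """One day of bucket hydrology: infiltration, ET, gravity drainage.

    Water enters at the surface (rain plus snowmelt, metres), fills layers
    top-down to field capacity, backs up to saturation against a frozen
    barrier (excess becomes runoff), evapotranspiration is withdrawn along
    the root profile from unfrozen layers, and excess above field capacity
    drains downward limited by unsaturated conductivity.  Frozen layers
    neither receive nor release liquid water.

    After drainage, capillary rise redistributes water upward between
    adjacent unfrozen layers wherever the suction gradient exceeds gravity,
    limited by the Darcy flux at the (wetter) source layer's conductivity and
    by one-sided matric equilibrium with the layer below.

    Returns ``(runoff_m, drainage_m, et_actual_m, balance_residual_m)``.
    """
    n = liq.shape[0]
    storage0 = 0.0
    for i in range(n):
        storage0 += liq[i] * dz[i]

    frozen = np.empty(n, np.bool_)
    for i in range(n):
        frozen[i] = (temps[i] <= 0.0) or (ice[i] > 1e-9)

    runoff = 0.0
    drainage = 0.0
    et_actual = 0.0

    barrier = n
    for i in range(n):
        if frozen[i]:
            barrier = i
            break

    # Infiltration to field capacity, top-down above the frozen barrier.
    w = water_in_m
    for i in range(barrier):
        if w <= 0.0:
            break
        cap = (theta_fc[i] - liq[i]) * dz[i]
        if cap > 0.0:
            add = cap if cap < w else w
            liq[i] += add / dz[i]
            w -= add
    if w > 1e-15:
        # Excess backs up toward saturation from the frozen barrier (or the
        # column bottom); what the column cannot hold becomes surface runoff.
        for i in range(barrier - 1, -1, -1):
            if w <= 0.0:
                break
            cap = (phi[i] - ice[i] - liq[i]) * dz[i]
            if cap > 0.0:
                add = cap if cap < w else w
                liq[i] += add / dz[i]
                w -= add
        if w > 0.0:
            runoff += w
            w = 0.0

    # Evapotranspiration: per-layer uptake is the root-share demand scaled
    # by a linear soil-moisture stress between wilting point and field
    # capacity; unmet demand is not reassigned to other depths.
    if et_pot_m > 0.0:
        for i in range(n):
            if frozen[i] or liq[i] <= theta_wp[i]:
                continue
            stress = (liq[i] - theta_wp[i]) / (theta_fc[i] - theta_wp[i])
            if stress > 1.0:
                stress = 1.0
            want = et_pot_m * root_frac[i] * stress
            avail = (liq[i] - theta_wp[i]) * dz[i]
            take = want if want < avail else avail
            liq[i] -= take / dz[i]
            et_actual += take

    # Gravity drainage of excess above field capacity.
    for i in range(n):
        if frozen[i]:
            continue
        excess = (liq[i] - theta_fc[i]) * dz[i]
        if excess <= 0.0:
            continue
        se = (liq[i] - theta_r[i]) / (phi[i] - theta_r[i])
        if se < 0.0:
            se = 0.0
        if se > 1.0:
            se = 1.0
        kcap = ksat[i] * se ** k_exp[i]
        flow = excess if excess < kcap else kcap
        if i < n - 1:
            if frozen[i + 1]:
                continue
            space = (phi[i + 1] - ice[i + 1] - liq[i + 1]) * dz[i + 1]
            if flow > space:
                flow = space
            if flow > 0.0:
                liq[i] -= flow / dz[i]
                liq[i + 1] += flow / dz[i + 1]
        else:
            liq[i] -= flow / dz[i]
            drainage += flow

    # Capillary rise against gravity.  The upward Darcy flux between layer
    # centres is evaluated with the Kirchhoff matric-flux potential
    # Phi(psi) = Ksat*psi_ae/(lam*eta - 1) * (psi/psi_ae)^(1 - lam*eta) of the
    # Brooks-Corey soil, which integrates the steep K(psi) over the gap and
    # so stays bounded into very dry soil; the gravity term uses the (wetter)
    # lower layer's conductivity.
    for i in range(n - 1):
        if frozen[i] or frozen[i + 1]:
            continue
        se_up = (liq[i] - theta_r[i]) / (phi[i] - theta_r[i])
        se_lo = (liq[i + 1] - theta_r[i + 1]) / (phi[i + 1] - theta_r[i + 1])
        if se_lo <= 1e-9:
            continue
        if se_lo > 1.0:
            se_lo = 1.0
        lk_up = bc_lambda[i] * k_exp[i]
        lk_lo = bc_lambda[i + 1] * k_exp[i + 1]
        # matric flux potentials (m^2 d^-1), each with its own layer's params
        if se_up <= 1e-9:
            mfp_up = 0.0
        else:
            if se_up > 1.0:
                se_up = 1.0
            psi_up = psi_ae[i] * se_up ** (-1.0 / bc_lambda[i])
            mfp_up = (
                ksat[i] * psi_ae[i] / (lk_up - 1.0)
                * (psi_up / psi_ae[i]) ** (1.0 - lk_up)
            )
        psi_lo = psi_ae[i + 1] * se_lo ** (-1.0 / bc_lambda[i + 1])
        mfp_lo = (
            ksat[i + 1] * psi_ae[i + 1] / (lk_lo - 1.0)
            * (psi_lo / psi_ae[i + 1]) ** (1.0 - lk_lo)
        )
        dzc = 0.5 * (dz[i] + dz[i + 1])
        k_grav = ksat[i + 1] * se_lo ** k_exp[i + 1]
        q = (mfp_lo - mfp_up) / dzc - k_grav  # m d^-1, upward positive
        if q <= 0.0:
            continue
        avail = 0.9 * (liq[i + 1] - theta_r[i + 1]) * dz[i + 1]
        space = (phi[i] - ice[i] - liq[i]) * dz[i]
        if q > avail:
            q = avail
        if q > space:
            q = space
        if q > 0.0:
            liq[i] += q / dz[i]
            liq[i + 1] -= q / dz[i + 1]

    storage1 = 0.0
    for i in range(n):
        storage1 += liq[i] * dz[i]
    residual = (storage1 - storage0) - (
        water_in_m - et_actual - runoff - drainage
    )
    return runoff, drainage, et_actual, residual


@njit(cache=True)
def moisture_factor_scalar(s, s_lo, s_opt_lo, s_opt_hi, f_sat):
    if s <= s_lo:
        return 0.0
    if s < s_opt_lo:
        return (s - s_lo) / (s_opt_lo - s_lo)
    if s <= s_opt_hi:
        return 1.0
    return 1.0 + (s - s_opt_hi) / (1.0 - s_opt_hi) * (f_sat - 1.0)


@njit(cache=True)
def carbon_day(
    oc,
    temps,
    liq,
    phi,
    k_day,
    q10,
    ref_temp,
    frozen_cutoff,
    s_lo,
    s_opt_lo,
    s_opt_hi,
    f_sat,
    heat_yield_j_per_kg,
    loss_out,
    heat_out,
):
    """One 24 h degradation step on the pool array ``oc`` (3, n), in place."""
    n = temps.shape[0]
    for i in range(n):
        if temps[i] > frozen_cutoff:
            ft = q10 ** ((temps[i] - ref_temp) / 10.0)
        else:
            ft = 0.0
        s = liq[i] / phi[i]
        if s > 1.0:
            s = 1.0
        if s < 0.0:
            s = 0.0
        fm = moisture_factor_scalar(s, s_lo, s_opt_lo, s_opt_hi, f_sat)
        loss = 0.0
        for p in range(3):
            before = oc[p, i]
            oc[p, i] = before * np.exp(-k_day[p] * ft * fm)
            loss += before - oc[p, i]
        loss_out[i] = loss
        heat_out[i] = loss * heat_yield_j_per_kg / SECONDS_PER_DAY


@njit(cache=True)
def run_simulation(
    air,
    precip_mm,
    et_pot_mm,
    dz,
    phi,
    hc_solids,
    kh_dry,
    kh_slope,
    kh_frozen_factor,
    theta_r,
    theta_fc,
    theta_wp,
    ksat,
    k_exp,
    psi_ae,
    bc_lambda,
    root_frac,
    temps,
    liq,
    ice,
    swe,
    rho_snow,
    oc,
    k_day,
    q10,
    ref_temp,
    frozen_cutoff,
    s_lo,
    s_opt_lo,
    s_opt_hi,
    f_sat,
    heat_yield_j_per_kg,
    heat_feedback,
    snow_enabled,
    n_sub,
    temp_out,
    liq_out,
    ice_out,
    oc_out,
    loss_out,
    swe_out,
    tsurf_out,
    runoff_out,
    drainage_out,
    et_out,
    energy_res_out,
    energy_turn_out,
    water_res_out,
):
    """Full daily loop; state arrays are advanced in place, outputs filled.

    Returns -1 on success, else the failing day index (heat non-convergence).
    """
    n_days = air.shape[0]
    n = dz.shape[0]
    source = np.zeros(n)
    day_loss = np.zeros(n)
    day_heat = np.zeros(n)

    for day in range(n_days):
        # Snow and surface boundary
        if snow_enabled:
            swe, rho_snow, rain, melt = snow_day(
                swe, rho_snow, air[day], precip_mm[day]
            )
        else:
            rain = precip_mm[day]
            melt = 0.0
        wtot0 = liq[0] + ice[0]
        fl0 = liquid_fraction(temps[0])
        top_kh = (kh_dry[0] + kh_slope[0] * wtot0) * (
            kh_frozen_factor[0] - (kh_frozen_factor[0] - 1.0) * fl0
        )
        t_surf = surface_temperature(
            air[day], swe, rho_snow, top_kh, dz[0], temps[0]
        )

        # Heat conduction with freeze-thaw
        wtot = liq + ice
        if heat_feedback:
            for i in range(n):
                source[i] = day_heat[i]
        flux, eres, eturn, flag = heat_day(
            temps,
            wtot,
            dz,
            phi,
            hc_solids,
            kh_dry,
            kh_slope,
            kh_frozen_factor,
            t_surf,
            source,
            n_sub,
            200,
        )
        if flag >= 0:
            return day
        partition_phase(temps, liq, ice)

        # Water redistribution
        water_in = (rain + melt) / 1000.0
        runoff, drainage, et_act, wres = water_day(
            liq,
            ice,
            temps,
            dz,
            phi,
            theta_r,
            theta_fc,
            theta_wp,
            ksat,
            k_exp,
            psi_ae,
            bc_lambda,
            water_in,
            et_pot_mm[day] / 1000.0,
            root_frac,
        )

        # Carbon degradation on daily-mean state
        carbon_day(
            oc,
            temps,
            liq,
            phi,
            k_day,
            q10,
            ref_temp,
            frozen_cutoff,
            s_lo,
            s_opt_lo,
            s_opt_hi,
            f_sat,
            heat_yield_j_per_kg,
            day_loss,
            day_heat,
        )

        for i in range(n):
            temp_out[day, i] = temps[i]
            liq_out[day, i] = liq[i]
            ice_out[day, i] = ice[i]
            loss_out[day, i] = day_loss[i]
            for p in range(3):
                oc_out[day, p, i] = oc[p, i]
        swe_out[day] = swe
        tsurf_out[day] = t_surf
        runoff_out[day] = runoff * 1000.0
        drainage_out[day] = drainage * 1000.0
        et_out[day] = et_act * 1000.0
        energy_res_out[day] = eres
        energy_turn_out[day] = eturn
        water_res_out[day] = wres * 1000.0

    return -1
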