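# cryoarch

Coupled soil heat, water and organic-carbon degradation model for Arctic
archaeological deposits.

Organic archaeological deposits in West Greenland — middens and occupation
layers from the Saqqaq, Dorset, Thule and Norse cultures — preserve wood,
bone, hair and ancient DNA only as long as microbial degradation stays slow.
Degradation is controlled by soil temperature and moisture during the
frost-free season, so a warming climate threatens these archives directly.
`cryoarch` is a self-contained simulator for this problem, aimed at
researchers in environmental archaeology and permafrost biogeochemistry who
want to rank site vulnerability: it couples a 1-D soil column (heat
conduction with freeze–thaw, snow insulation, bucket hydrology with
capillary redistribution and evapotranspiration) to a three-pool
organic-carbon decay model, and drives it with synthetic daily weather for
sites along the region's coastal–inland climate gradient under present-day
and RCP 4.5 / RCP 8.5 warming.

## Model

Total soil respiration per layer is the sum of three first-order pool
rates (Eq. terms per pool *i* ∈ {fast, slow, passive}):

```
R = Σᵢ rᵢ = Σᵢ kᵢ · a(T) · m(S) · OCᵢ ,   fᵢ = OCᵢ / OC_tot
```

* pool fractions at initialisation: 5 % fast, 50 % slow, 45 % passive; the
  archaeological carbon resides in the slow pool;
* `kᵢ = 1/τᵢ` with turnover times τ = 1, 50 and 4000 years at the reference
  state (5 °C, drained);
* `a(T) = Q10^((T−5)/10)` with Q10 = 2.3, zero at or below 0 °C;
* `m(S)` is a piecewise-linear response in degree of saturation
  (desiccation cutoff, optimum band, decline to 0.3 at saturation);
* each kg of carbon mineralised releases 40 MJ of microbial heat, which can
  optionally be fed back into the heat budget.

Pools are updated daily by the exact exponential solution, so trajectories,
e-folding times and the Q10 ratio are reproduced to machine precision.

The thermal column is 5 m deep in 64 layers (21 in the upper metre, which
carries the deposit's cross-site mean properties: porosity 77.1 %,
loss-on-ignition 30.3 %, bulk density 458 kg m⁻³). Heat conduction is solved
hourly with an enthalpy formulation (latent heat spread over [−0.5, 0] °C);
precipitation falls as snow below 0.5 °C air temperature and the snowpack
insulates the surface through a conductance-weighted boundary temperature.
Water follows a daily bucket cascade with Brooks–Corey/Mualem retention and
conductivity, field capacity at 1 m head, a 140-day growing season with
4 mm day⁻¹ potential evapotranspiration, and Kirchhoff-type capillary rise.

An incubation module mirrors the laboratory side: it fits oxygen-decline
slopes from closed vials, estimates Q10 by log-linear regression across 1,
5, 10 and 15 °C runs, converts O₂ to carbon (1 mol O₂ : 1 mol C), and checks
measured basal rates against the pool model's prediction.

## Worked example

Simulate the inland site preset for a decade (three spin-up years are
discarded automatically) and summarise conditions in the archaeological
layer at 0.4 m:

```python
import cryoarch as ca

profile = ca.build_default_profile()
site = ca.DEFAULT_PRESETS[4]                       # "inland"
forcing = ca.generate_forcing(site, 2014, 2026, seed=42)
result = ca.simulate(profile, forcing)

print("TDD at 0.4 m:", round(ca.tdd(result.temp_at(0.4)).iloc[-5:].mean(), 1))
print("frost-free days:", round(float(
    ca.frost_free_duration(result.temp_at(0.4)).iloc[-5:].mean()), 1))
print("annual slow-pool loss (%/yr):", round(
    ca.annual_slow_loss(result, 0.4).iloc[-5:].mean(), 2))
```

prints

```
TDD at 0.4 m: 789.2
frost-free days: 175.4
annual slow-pool loss (%/yr): 0.8
```

i.e. the layer at 0.4 m accumulates ~789 thawing degree days per year, is
unfrozen for ~175 days, and loses ~0.8 % of its slow (archaeological)
carbon pool per year under present-day forcing. The full five-site ×
scenario experiment is one call, `ca.run_projection(seed=42)`, which
returns a tidy summary table; the same runs are exposed on the command line
via `cryoarch project`, with `synth-forcing`, `simulate` and
`incubation-fit` subcommands for the individual stages.

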