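# Methods

## Scope and model structure

`cryoarch` simulates the oxic microbial degradation of organic
archaeological deposits in a seasonally frozen soil column. One simulation
couples four parts on a daily loop: a snow scheme setting the surface
boundary, 1-D heat conduction with freeze–thaw, a bucket hydrology, and
three-pool first-order carbon kinetics. A synthetic-forcing generator
supplies daily weather for idealised sites along a maritime-to-continental
gradient, and a projection driver runs the site × scenario factorial and
reduces it to the summary metrics (thawing degree days, frost-free
duration, annual and cumulative slow-pool loss).

## Carbon kinetics

Each layer's organic carbon (bulk density × loss-on-ignition × 0.5; the
0.5 is the conventional organic-matter-to-carbon ratio) is split 5/50/45 %
into fast, slow and passive pools with turnover times 1, 50 and 4000 years
at the reference state of 5 °C and drained moisture. ">4000 years" for the
passive pool is implemented as exactly 4000 — an upper bound on its rate
whose contribution is negligible either way. Rates scale with temperature
as Q10 = 2.3 (zero at or below 0 °C — degradation is framed by the
frost-free period) and with moisture through a piecewise-linear function of
degree of saturation S. Pools are decremented by the exact exponential
factor `exp(-k·a(T)·m(S)·Δt)` each 24 h step rather than a forward-Euler
product: the exact update preserves the closed-form trajectory (and hence
the 50-year e-folding of the slow pool and the Q10 ratio of instantaneous
respiration) to machine precision, and the two differ by less than 0.2 %
per year for the fastest pool. The fractionation coefficients fᵢ therefore
evolve as pools deplete, which is the only mass-conserving reading of the
pool formulation.

### Moisture response

The response is zero below S = 0.108, rises linearly to 1 at S = 0.144, is
optimal up to S = 0.7, and declines linearly to 0.3 at saturation (oxygen
limitation). The dry-limb breakpoints are anchored in matric potential,
where microbial desiccation physiology actually operates — activity ceasing
near pF 5.7 and optimal wetter than about pF 3.7 — and mapped into S
through the deposit's own Brooks–Corey retention curve. Anchoring the dry
limb at a much wetter point (for example at field capacity, around S ≈ 0.39
for this soil) would label the entire unsaturated summer operating range of
the deposit moisture-limited and invert the observed coastal–inland
contrast; see Limitations.

### Microbial heat

Mineralisation releases 40 MJ per kg C (≈ 480 kJ per mole of carbon
oxidised, the aerobic-respiration enthalpy). With the feedback flag on,
the previous day's loss enters the heat equation as a volumetric source.
The flag defaults to off; see Limitations for why this term is not small
under the canonical pool rates.

## Soil column

Default grid: 5 m in 64 layers; the upper 1 m (21 uniform layers of
~4.76 cm) is the archaeological deposit with cross-site mean properties
(porosity 0.771, LOI 0.303, bulk density 458 kg m⁻³); below it, 43
geometrically stretched layers of mineral cryosol (porosity 0.40, LOI 0.02,
1500 kg m⁻³). Hydraulics are Brooks–Corey retention with Mualem
conductivity `K = Ksat·Se^(2.5+2/λ)`; organic deposit: air entry 0.1 m,
λ = 0.5, θr = 0.08, Ksat = 1 m d⁻¹; mineral: 0.3 m, 0.3, 0.05, 0.1 m d⁻¹.
Thermal conductivity is linear in volumetric water (organic: 0.10 +
0.9·θ W m⁻¹ K⁻¹, matching the strong positive field correlation with water
content; mineral: 0.70 + 1.8·θ), multiplied by 1.5 when frozen; heat
capacity mixes solids (2.5 / 2.0 MJ m⁻³ K⁻¹ organic/mineral), water
(4.18) and ice (1.9) volumetrically.

## Heat transport and freeze–thaw

Conduction is solved in 24 hourly implicit substeps per day with a
Dirichlet surface temperature and zero flux at 5 m. Phase change uses an
apparent-heat-capacity (enthalpy) formulation: enthalpy is piecewise linear
in temperature, with the latent heat of the layer's total water spread over
[−0.5, 0] °C. Each substep solves the nonlinear balance by semismooth
Newton iteration with a backtracking line search on the residual norm
(tolerance 10⁻⁶ W m⁻² per layer, 200 iterations maximum; failure raises a
`ConvergenceError` with the offending date). Plain Picard iteration — with
either local or chord apparent capacities — two-cycles across the freezing
breakpoints and was abandoned. At convergence the discrete enthalpy balance
holds exactly, so energy is conserved by construction; residuals are
accumulated per day and exposed on the result (`energy_residual` /
`energy_turnover`), and the suite checks them against a 0.1 % bound along
with the semi-infinite step-change erf solution (≤ 0.1 °C at day 30).

## Surface boundary and snow

Snow-free ground takes the daily mean air temperature as its surface
temperature — a deliberate simplification of a radiation-based surface
scheme, since the forcing carries no radiation terms. Precipitation is snow
below 0.5 °C air temperature; melt is degree-day (3 mm w.e. °C⁻¹ d⁻¹);
fresh snow falls at 150 kg m⁻³ and compacts toward 350 kg m⁻³ at 2 % of the
deficit per day. Under snow, the surface temperature is the conductance-
weighted interface value `w·T_air + (1−w)·T_top` with
`w = (k_snow/d_snow)/(k_snow/d_snow + k_soil/d_soil)` and
`k_snow = 0.021 + 2.5(ρ/1000)²` — the series-resistance interface
temperature, so insulation deepens with snow depth and lightness.

## Water

A daily bucket cascade stands in for a Richards solver: infiltration fills
layers to field capacity (retention at 1 m head) top-down, backs up toward
saturation against a frozen barrier or the column bottom, and sheds the
remainder as runoff; gravity drainage moves water above field capacity
downward at the unsaturated conductivity, leaving the column only through
the bottom layer. Frozen layers exchange no liquid. Two processes beyond
the minimal cascade proved necessary for a defensible moisture climate:

* **Root-uptake stress.** Evapotranspiration (potential 4 mm d⁻¹ during the
  140-day growing season, days 152–291; 0.5 mm d⁻¹ otherwise) is
  distributed along an exponential root profile (90 % above 0.3 m) and
  scaled per layer by a linear stress between the wilting point (150 m
  head) and field capacity, without compensatory reassignment of unmet
  demand. Unrestricted `min(potential, available)` extraction strips the
  entire column to residual water within one season via the capillary
  pathway below.
* **Capillary rise.** Upward flux between adjacent unfrozen layers is the
  gravity-corrected Darcy flux evaluated with the Kirchhoff matric-flux
  potential `Φ(ψ) = Ksat·ψae/(λη−1)·(ψ/ψae)^(1−λη)`, which integrates the
  steep K(ψ) across the gap and therefore remains bounded into very dry
  soil. Without it a bucket model dries mid-column layers to residual
  directly above a wet subsoil, which strong-capillarity organic media do
  not do.

Mass balance closes to the 10⁻⁶ mm level per day and is checked in the
suite.

## Synthetic forcing and scenarios

Air temperature is a sinusoid (minimum in late January, maximum in late
July) plus AR(1) noise (lag-1 correlation 0.7, marginal SD 2.5 °C).
Precipitation falls on random days (wet-day probability 0.3) with
exponential amounts whose seasonal means reproduce the annual total and its
June–August share in expectation. Five presets span the gradient with
continentality 0, 0.25, 0.5, 0.75, 1: mean annual air temperature −1.5 →
+0.5 °C, amplitude 9 → 14 °C, precipitation 800 → 350 mm, summer share
0.35 → 0.45 (continental climates peak in summer). These produce roughly
twice the airborne thawing degree days inland as at the outer coast and
substantially less rain — the regional contrast the presets are meant to
emulate. Warming scenarios add seasonal deltas (RCP 4.5: DJF 3.1, MAM 2.5,
JJA 2.0, SON 2.5 °C; RCP 8.5: 6.0, 5.0, 3.9, 5.0 °C at 2100) ramped
linearly from 2017 to 2100 — only endpoint deltas are available, so the
ramp shape is a choice — with precipitation left at present-day rates.

What the generator does *not* emulate: radiation and wind, weather-regime
persistence beyond AR(1), precipitation–temperature correlation, wind
redistribution of snow, and interannual climate modes. Passing bracket
checks with these presets therefore shows internal consistency of the
coupled model under plausible forcing, not skill against any particular
observed site.

## Simulation conventions

Runs start from a uniform temperature equal to the snow-adjusted mean
annual *surface* temperature of the first forcing year (estimated by
pre-running the snow scheme with the ground held at 0 °C), water at field
capacity, and phase partition consistent with temperature. Initialising at
the mean *air* temperature instead starts coastal columns (MAAT −1.5 °C)
inside a spurious permafrost body that three spin-up years cannot clear,
because thawing it must pay the full latent heat. The first three calendar
years of every run are spin-up and are removed from the returned result;
projection windows (for example 2017–2100) therefore begin with forcing
from 2014. Yearly loss windows run from a year's first day to the next
year's first day, so adjacent windows compose multiplicatively. "At 0.4 m"
means the layer whose interval contains 0.4 m; depth-integrated losses
weight layers by the thickness overlapping the 0–0.5 m band.

## Projection experiment

`run_projection` crosses the five presets with {none, RCP4.5, RCP8.5}.
The `none` runs cover ten post-spin-up years and define present-day
baselines as means over their final five years; the RCP runs cover
2014–2100 and additionally report cumulative 2017–2100 slow-pool losses.
Per-site forcing seeds derive deterministically from the experiment seed.
On one CPU the factorial takes roughly a minute.

## Incubation analysis

Respiration rates are ordinary-least-squares slopes of headspace O₂ against
time over the full measured window (no lag-phase trimming), negated and
normalised by dry mass; Q10 comes from the log-linear regression of ln(rate)
on temperature across all four run temperatures (reducing to the pairwise
ratio with two), with a t-based interval when more than two temperatures
remain. O₂ converts to carbon by the 1:1 molar assumption (12.011/31.998
by mass). `check_pool_consistency` compares a measured basal rate with the
pool model's implied specific respiration at 5 °C drained and returns the
uniform rate rescaling that would reconcile them; projections default to
the canonical, unrescaled turnovers, and the rescaling is exposed as
`SimulationOptions.rate_scale` for sensitivity work.

## Known limitations

* **Absolute rate inconsistency.** The canonical pools predict a specific
  respiration of ~0.025 mg C g⁻¹ d⁻¹ at 5 °C drained for the mean deposit,
  ~3.7× the measured mean basal rate the same kind of incubation yields
  (0.018 mg O₂ ≈ 0.0068 mg C g⁻¹ d⁻¹). The package reports this ratio
  rather than hiding it; percentage-loss metrics are insensitive to a
  uniform rescaling of all three rates, but absolute fluxes — and
  microbial heat — are not.
* **Microbial heat feedback is not negligible here.** At canonical rates
  the warm-season source reaches ~2–4 W m⁻³ in a 0.37 W m⁻¹ K⁻¹ organic
  metre (steady ΔT ≈ S·L²/2k of order degrees), and the OC-bearing subsoil
  above a zero-flux bottom boundary adds a slow secular warming with an
  outright unstable Q10 feedback (the compost effect). Enabling the
  feedback flag therefore changes summary metrics by tens of percent, and
  the corresponding negligibility check in the acceptance suite fails by
  design rather than being weakened. A geothermal-flux bottom boundary and
  inert subsoil carbon would damp this; both are out of scope.
* The bucket hydrology reproduces a plausible moisture climate but not
  absolute water contents; no water table, vapour flux or Richards dynamics.
* No site calibration: thermal conductivity, which field work shows must be
  calibrated per site, uses one regional default, so simulated soils run
  somewhat warm relative to calibrated site models — visible as bracket
  maxima a few tens of percent above published upper bounds in the
  acceptance checks.
* Single organic-carbon currency: no differential kinetics for specific
  artefact materials, no anoxic pathway, no plant-carbon input offset.
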