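# Methods

## Scope and intent

`baltfate` is a reduced-form, desk-scale analogue of the class of coupled
hydrodynamic–biogeochemical–contaminant models used for chemicals management
in the Baltic Sea. It is deliberately small — three named basins, two layers
each, daily explicit time stepping — and aims to reproduce *mechanisms and
scenario logic* (which emission control works, why sea ice produces winter
concentration peaks, how warming and eutrophication modulate the answer),
not the calibrated output of any full-scale model. Magnitudes quoted for
full-scale systems are treated as directional expectations only.

## Physical model

Each basin has a fixed-geometry surface and deep layer (rigid lid, constant
volumes). Freshwater enters as river discharge plus net precipitation
(evaporation is a fixed fraction of precipitation, default 0.8 — the water
balance, not the heat balance, is what the contaminant model needs). A
parameterized deep inflow of salty boundary water (rate and salinity per
basin) enters the deep layer, is entrained upward at the same rate, and the
total surplus leaves as surface outflow along the basin chain toward the
single open boundary. This is a deliberately coarse stand-in for the
salt-water intrusion cascade of a real estuarine sea; volumes are conserved
exactly by construction and salt is conserved up to the declared boundary
fluxes (machine precision per step).

Surface temperature relaxes toward air temperature with τ = 14 d plus an
absorbed-shortwave heating term; the deep layer relaxes toward the surface
with τ = 120 d. Sea ice is a freezing-degree-day (FDD) model: once the
surface water sits at its salinity-dependent freezing point
(T_f = −0.054·S), days with air temperature below T_f accumulate the FDD
reservoir; ice fraction = min(1, FDD/100 °C·d). Days with air above T_f
deplete the reservoir at 3–5× the freezing efficiency (default melt factor
4) — spring melt is driven largely by shortwave absorption that the
air-temperature surplus understates, and degree-day models conventionally
use a larger melt than freeze coefficient. The reservoir saturates at
150 °C·d: ice cover (the quantity that blocks gas exchange and light) stops
responding to additional winter cold long before the underlying ice sheet
stops thickening. With the default climatology this yields ~150–190 ice
days per year in the Bothnian Bay analogue with breakup in late April/May,
no ice in the Fehmarn Belt analogue, and Gotland Sea ice only in
anomalously cold years — the qualitative Baltic pattern.

## Biogeochemistry

A single phytoplankton group grows at
μ = μ_max · Q10^((T−20)/10) · min(N/(N+K_N), P/(P+K_P)) · I/(I+K_I),
consuming DIN and DIP in Redfield mass proportion (C:N:P = 41:7.2:1).
Irradiance is a fixed fraction (0.25) of surface shortwave, further blocked
by ice cover. Mortality (0.05 d⁻¹ at 20 °C, Q10-scaled so a small stock
overwinters) routes biomass to detritus with a 10 % DOC exudation branch;
the exuded fraction's N and P return directly to the inorganic pools so DOC
carries carbon only. Detritus remineralizes (0.03 d⁻¹ at 20 °C, Q10 = 2)
and sinks at 1.5 m/d through the deep layer into a sediment organic-carbon
pool, which mineralizes back to the bottom water and buries. Rivers carry
DIN and DIP loads and DOC at a fixed concentration; the deep boundary inflow
carries prescribed nutrient and DOC concentrations.

Parameter values are literature-typical magnitudes, not a calibration. The
default basin configurations place the Gotland Sea analogue in a
nutrient-limited (P-limited) regime where detritus tracks nutrient loads,
and the Bothnian Bay analogue in a cold, dim, genuinely oligotrophic regime
whose particulate carbon responds much less, absolutely and relatively, to
the same relative load change — the contrast that makes eutrophication
scenarios interesting for contaminant fate. Nitrogen and phosphorus budgets
(water + sediment + boundary/burial ledgers) close to machine precision;
the 0.1 % acceptance band is a safety margin, not the observed error.

## Contaminant model

State: bulk-water total concentration per layer (ng/L) and a sediment
active-layer pool (2 cm, 250 kg dm/m³ dry bulk density). Within a parcel
the chemical partitions instantaneously:

    f_diss = 1/(1 + K_DOC·DOC + K_OC·POC),     sorbents in kg C/L,

with f_DOC and f_POC proportional to their terms. K_DOC = 0.1·K_OC.

Temperature corrections use van't Hoff factors
K(T) = K_25 · exp(ΔU/R · (1/T − 1/298.15)). ΔU_AW (−30 kJ/mol) is defined
as the internal energy of **dissolution** (air→water transfer), so the
negative default gives the physically expected lower volatility (smaller
K_AW) in cold water; ΔU_OW (−20 kJ/mol) is the energy of the
water→organic-phase transfer and gives stronger sorption in cold water.
Degradation rate constants use the Arrhenius form
k(T) = k_25 · exp(−E_a/R · (1/T − 1/298.15)).

Processes, applied in a fixed daily operator-splitting order so runs are
bit-reproducible (advection → air–water exchange → transformation →
settling/sediment; the splitting error is O(dt) and small because all rates
are ≪ 1/d):

* **Advection** — total concentration rides every water flow; rivers inject
  the contaminant load into surface layers; the open-boundary outflow
  removes mass permanently.
* **Air–water exchange** — two-film model with wind-driven film velocities
  k_a = 10⁻³(0.3 + 0.2·u₁₀) m/s and k_w = 0.17·10⁻⁶·u₁₀² m/s (floor
  10⁻⁷ m/s); both gross directions scale with open-water fraction
  (1 − ice), the paper-mechanism switch behind the winter peak. Gross
  absorption and volatilization are ledgered separately.
* **Transformation** — hydrolysis attacks the dissolved phase only
  (particle-bound chemical is protected); aqueous biodegradation (default 0
  for D5) attacks dissolved + DOC; sediment degradation attacks the whole
  sediment pool.
* **Settling/sediment** — POC-bound mass sinks with the detritus velocity;
  the sediment resuspends (10⁻⁴ d⁻¹), buries (5·10⁻⁵ d⁻¹) and exchanges
  dissolved chemical with the bottom water through a 10⁻² m/d diffusive
  velocity acting on the pore-water (K_OC equilibrium with sediment OC)
  versus dissolved-concentration difference.

Every process is linear in the contaminant state for fixed physics and
biogeochemistry, so scaling all contaminant inputs by α scales every
concentration by α to machine precision — the property that makes "a 90 %
load cut gives a 90 % concentration cut" exact up to the small atmospheric
input and the sediment-memory transient.

D5 property defaults (log K_OW 8.1, log K_AW 3.1, log K_OC 5.2, hydrolysis
t½ 65 d at 25 °C with E_a 90 kJ/mol, aqueous biodegradation 0, sediment
t½ 1200 d) follow the EU risk-assessment property profile of the compound;
all are configurable through the chemical card.

## Forcing and scenarios

The RW generator produces, per basin and variable, a sinusoidal seasonal
cycle plus one Gaussian annual anomaly per year (AR(0)), clipped at zero for
non-negative variables — the simplest stationary "random weather". The same
seed reproduces the identical series bitwise. Default climatologies are
round Baltic-like magnitudes (e.g. Bothnian Bay air temperature 3 ± 11 °C
seasonal, σ = 0.8 °C interannual; Gotland Sea 7 ± 7 °C; winds ~7–8 m/s
peaking in winter; spring-flood discharge and load seasonality). River
contaminant loads (30 kg/d Gotland Sea, 5 kg/d elsewhere) against a 1 ng/m³
atmospheric concentration give riverine dominance of the input budget by
~10⁵, a hypothetical but internally consistent emission picture.

Scenario transforms:

* **a1b** — wind ×1.07 and precipitation ×1.20 applied multiplicatively to
  every value; air temperature shifted **additively** by (1.60 − 1) × the
  realized per-basin period mean, so the period-mean ratio equals 1.60
  exactly for any weather realization while winters warm by the same delta
  as summers. A literal multiplicative mode (`temperature_mode="scale"`)
  exists but is not the default: multiplying signed °C values by 1.6 makes
  sub-zero winters *colder* and ice seasons longer, inverting the warming
  signal the scenario is meant to carry.
* **CL/IL/BSAP** — nutrient-load multipliers: constant; linear ramp to 1.5×
  by 2100; linear ramp to 0.6× by 2021 then constant. Ramp targets and end
  years are configurable (the defaults are round placeholders for
  policy-path tables, not data).
* **current/red_river/red_air** — step multiplication of the river
  contaminant load or the atmospheric concentration by (1 − reduction
  fraction) from 1 January of the reduction year (default 0.9 from 2006).
  Atmospheric contaminant is a prescribed concentration, not an emission
  flux — the natural reading of an "air concentration reduction" scenario.

Emission and nutrient transforms act on disjoint forcing fields and commute
exactly. Scenario comparisons run every member on the same RW realization
(shared seed), so contrasts are paired and weather noise cancels.

## What the synthetic forcing does and does not represent

The generator emulates seasonal amplitude, interannual variability and the
relative magnitudes of Baltic forcing; it does not contain weather
autocorrelation within years, trends, extreme events, reanalysis data or
real load compilations. Consequently, passing tests demonstrate that the
*model machinery* reproduces the stated mechanisms under controlled,
Baltic-like conditions — not that the numbers match any observed Baltic
time series. Full-scale results (e.g. specific percentage differences
between eutrophication scenarios at end-of-century) depend on calibrated
limitation structure and are outside this model's claims.

## Numerical choices

Explicit Euler, dt = 1 day, 365-day no-leap calendar. Stability is
guaranteed by parameter bounds (all loss rates ≪ 1/d; growth and
mineralization terms are capped per step so pools cannot go negative).
Tendencies are evaluated at start-of-step states, making every transfer
exactly conservative in the budget ledgers; budget closure is checked at
run end against a relative tolerance (default 10⁻³) and a breach raises an
abort carrying the full budget dump. Peak-month ties break toward the
earliest month; all-zero concentration years report an undefined (NaN)
winter amplitude rather than raising. The "winter" reporting season is
December–April.

## Problem sizes

Default experiments are sized for a single CPU: the paired emission
experiment runs 3 basins × 41 years × daily steps (~15 000 steps) in well
under a minute per run; budget-closure checks use a 100-year run; climate
and eutrophication contrasts use 8–12-year paired runs, long enough to
average over several ice seasons and bloom cycles.

## Known limitations

No resolved inter-basin deep-water cascade or inflow events; no seasonal
thermocline migration; single phytoplankton group, no zooplankton, oxygen,
silica or N-fixation; no carbonate system; sediment is a single well-mixed
active layer; air concentration is forcing, not state (no atmospheric
transport); neutral organics only — ionizing chemicals and metals are out
of scope; no food-web bioaccumulation. The a1b transform applies constant
factors over the scenario period (an optional ramp is a natural extension
but is not implemented).
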