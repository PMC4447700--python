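# baltfate

A desk-scale, multi-basin box model of organic-contaminant fate in a
semi-enclosed brackish sea under **multistressor scenarios** — combined
changes in chemical emissions, nutrient loads (eutrophication) and climate.
It is built for the question chemicals managers actually ask: *which
emission-reduction measure lowers environmental concentrations the most, by
how much, and how is the answer modulated by the other stressors?*

The model couples four layers of process description on a shared daily loop:

1. **Physics** — two-layer basins connected in a chain draining to an open
   boundary; exact water and salt balances; surface heat relaxation; a
   freezing-degree-day sea-ice model.
2. **Biogeochemistry** — a nutrient–phytoplankton–detritus (NPD) model with
   DOC and POC pools, Redfield stoichiometry, sinking, and a sediment
   organic-carbon pool. Its job is to supply dynamic sorbent concentrations.
3. **Contaminant mass balance** — for a neutral organic chemical:
   equilibrium three-phase partitioning (dissolved / DOC-bound / POC-bound),
   two-film air–water exchange blocked by sea ice, hydrolysis of the
   dissolved phase, biodegradation, particle settling, sediment
   resuspension/burial/diffusion, and inter-basin advection.
4. **Scenarios** — a seeded "random weather" (RW) generator plus transforms:
   an A1B-type warming (`a1b`: +7 % wind, +60 % air temperature on the
   period mean, +20 % precipitation), nutrient-load paths (`CL` constant,
   `IL` increasing, `BSAP` action-plan reductions) and emission controls
   (90 % cuts of river loads or atmospheric concentrations from 2006).

The default chemical card is **decamethylcyclopentasiloxane (D5)**, a cyclic
volatile methylsiloxane: log K_OW 8.1, log K_AW 3.1, log K_OC 5.2,
hydrolysis half-life 65 d at 25 °C, negligible aqueous biodegradation, and
persistence when particle-bound. These properties produce the model's
characteristic behaviours: volatilization dominates losses (net flux is
sea→air, so cutting *air* concentrations is futile), river loads control
water concentrations, and seasonal ice cover shuts off volatilization and
produces a late-winter concentration peak in the ice-covered northern basin.

## Core quantities

For each basin the model reports `C_W`, the dissolved surface concentration
per litre of bulk water (ng/L),

```
C_W = f_diss · C_total ,   f_diss = 1 / (1 + K_DOC·[DOC] + K_OC·[POC])
```

with sorbent concentrations in kg C/L and partition coefficients corrected
to water temperature by van't Hoff factors. Air–water exchange follows the
two-film model,

```
k_OL = (1/k_w + 1/(k_a·K_AW))⁻¹ ,
F    = k_OL · (C_air/K_AW − C_diss) · (1 − ice fraction) ,
```

and a full mass budget (river input, absorption, volatilization, hydrolysis,
biodegradation, settling, resuspension, burial, boundary advection) is kept
and checked for closure at the end of every run — a breach aborts the run.

## Worked example

Compare the two emission-control options for D5 on a paired weather
realization (identical weather in both runs, so differences are purely
scenario-driven):

```python
import baltfate as bf
from baltfate.analysis import measure_effectiveness, winter_peak_stats

control = bf.SimulationConfig(start_year=1990, end_year=2030, seed=1)
treated = control.with_scenario(
    bf.ScenarioSpec(emissions="red_river", reduction_year=2006,
                    reduction_fraction=0.9))
o_c = bf.run_simulation(control)
o_t = bf.run_simulation(treated)

for basin in ("gotland_sea", "bothnian_bay"):
    eff = measure_effectiveness(o_c, o_t, basin, (2015, 2025))
    print(f"{basin}: river-load cut effectiveness {eff:.1f} %")

print(winter_peak_stats(o_c, "bothnian_bay").loc[2010:2014])
```

prints

```
gotland_sea: river-load cut effectiveness 90.0 %
bothnian_bay: river-load cut effectiveness 90.0 %
      peak_month  amplitude
year
2010           4   5.175725
2011           4   5.502966
2012           4   4.891747
2013           4   4.753988
2014           4   5.095853
```

Cutting river loads by 90 % lowers decadal-mean `C_W` by 90 % in both
basins, because riverine input dominates atmospheric absorption by a factor
of ~10⁵ and the contaminant balance is linear in its inputs. The winter-peak
table shows the ice mechanism: every year the Bothnian Bay `C_W` maximum
falls in April at 5–6× the summer minimum — volatilization, the dominant
loss, is blocked while the basin is ice-covered, and concentrations build up
until breakup. The same comparison with `emissions="red_air"` changes `C_W`
by well under 1 %.

## Command line

```bash
baltfate run --config config.yaml --out run_dir      # one simulation
baltfate compare --configs a.yaml --configs b.yaml --out cmp_dir
baltfate budget --run run_dir                        # print mass budget
baltfate analyze --config a.yaml --metrics decadal,peaks,ice --out metrics
```

Outputs are tidy CSV (`year, month, basin, variable, value`), a budget JSON
and a provenance block (config hash, seed, version); `--netcdf` adds a
`time × basin` NetCDF file.

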