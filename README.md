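# peatflux

National-scale peatland greenhouse-gas accounting for Canada: harmonize
heterogeneous CO2 and CH4 flux reports to a common basis, synthesize a
rule-based raster peatland map, and upscale ecozone × peatland-type emission
factors to seasonal and annual budgets with uncertainty.

## The problem

Canadian peatlands (bogs, poor fens, rich-intermediate fens) cover on the
order of 10^6 km², yet national estimates of their net ecosystem exchange
(NEE, with negative values denoting CO2 uptake) and CH4 emissions have
historically used a single emission factor for all peatlands. Plot studies —
chamber and eddy-covariance — report fluxes on inconsistent bases (daily,
growing-season, annual) across microforms (hummock, hollow, lawn), and no
national map separates rich from poor fens or open from treed/forested cover.

`peatflux` implements the full estimation chain for researchers compiling
such syntheses:

1. **harmonize** — classify sites (bog / poor fen / rich fen from hydrology,
   pH ≥ 5.5, and moss composition) and convert every reported value to a mean
   daily growing-season rate:

   `daily NEE = seasonal NEE / GS × 5` (g CO2 m⁻² day⁻¹)

   `daily CH4 = seasonal CH4 / GS × 1000` (mg CH4 m⁻² day⁻¹)

   where GS is the growing-season length in days and the factor 5 corrects
   for shoulder-season exchange. Annual values are first reduced to seasonal
   by removing an assumed winter emission (0.9 g CO2 m⁻² day⁻¹; 7 mg CH4
   m⁻² day⁻¹). Records are pooled into ecozone × class means with
   SE = s/√n, and empty cells are borrowed from the most similar ecozone.
2. **season** — growing season from daily temperature series: first 5-day
   run with mean ≥ 5 °C (from March 1) to the first minimum < −2 °C (from
   August 1).
3. **mapgen** — a 250 m nine-class peatland map (open/treed/forested ×
   bog/poor fen/rich fen) from a layer stack: water mask → peatland
   probability ≥ 0.5 → open-wetland landcover evidence → upland, with
   tamarack biomass fraction (< 10%, 10–25%, > 25%) separating the nutrient
   gradient; majority resampling for 30 m → 250 m evidence; area tabulation.
4. **assess** — confusion matrices with producer's/user's accuracy and
   Cohen's kappa; polygon-level percentage-bin agreement between maps.
5. **upscale** — seasonal EF per ecozone (reversing the daily conversion),
   × mapped area → Mt season⁻¹; SEs propagate linearly (sums) by default;
   CH4 × 25 → CO2-equivalents (GWP-100); winter constants annualize; a
   growing-season-length scenario rescales seasonal budgets.
6. **synth** — seed-deterministic synthetic flux records, climate series,
   raster landscapes (with an independent rule-oracle map) and validation
   points, so the whole chain runs and is testable without any downloads.

## Worked example

Reconstructing the national seasonal budget from per-class components
(Mt per growing season; SEs combine linearly):

```python
from peatflux import refdata
from peatflux.upscale import combine_emissions, net_emission

nee  = combine_emissions(refdata.BUDGET_NEWMAP["NEE"].values())
ch4e = combine_emissions(refdata.BUDGET_NEWMAP["CH4_CO2e"].values())
print(net_emission(nee, ch4e))
```

prints `(-7.0, 77.7)`: the three class NEE sinks
(−76.0, −22.6, −10.2) total −108.8 ± 41.3 Mt CO2 season⁻¹, CH4 as
CO2-equivalents adds +101.8 ± 36.4, and the country's peatlands come out a
marginal net sink of −7.0 Mt CO2e season⁻¹ whose SE (±77.6 printed, ±77.7
from the rounded components) dwarfs the estimate.

The synthetic pipeline end to end:

```bash
peatflux all --seed 42 --out run/
```

runs simulate → season → harmonize → buildmap → assess → upscale and writes
`emission_factors.csv`, `class_map.tif`, `confusion_matrix.csv` and
`budget_report.csv` plus a `run_log.json` recording every constant and seed.
The numbered drivers under `analysis/` run the same stages with commentary
and leave their tables under `results/`.

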