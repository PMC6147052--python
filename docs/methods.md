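# Methods

## Flux harmonization

The base unit of comparison is the mean **daily growing-season flux**:
g CO2 m⁻² day⁻¹ for NEE (negative = net uptake) and mg CH4 m⁻² day⁻¹ for
CH4. A daily basis controls for large differences in growing-season (GS)
length between study locations and admits studies that only report daily
values.

Conversions, with GS in days:

- seasonal → daily NEE: `daily = seasonal / GS × k` with `k = 5`. The
  scaling factor compensates for shoulder-season exchange that seasonal
  campaign totals miss; it is a fixed configurable constant here — re-fitting
  it from paired daily/seasonal studies is out of scope.
- seasonal → daily CH4: `daily = seasonal / GS × 1000` (g → mg; no scaling
  factor).
- annual → seasonal: subtract an assumed constant non-growing-season
  emission over `365 − GS` days. Defaults: **0.9 g CO2 m⁻² day⁻¹** and
  **7 mg CH4 m⁻² day⁻¹**. The CO2 literature compilation in
  `refdata.WINTER_CO2_STUDIES` has a simple mean of 0.94 → 0.9 at one
  decimal; the CH4 compilation averages 6.83 across rows (6.64 across
  studies), and 7 is the rounded operational constant. Both are
  `Constants` fields. An alternative convention (winter = 15% of growing
  season flux) appears in inventory guidance but is not implemented as the
  default here because ecosystem-respiration data needed for it are
  typically absent from the compiled studies.

`daily_to_seasonal` is the exact algebraic inverse of the two forward
conversions; a property test holds the round trip to < 1e−9 relative error.

**Site classification.** Bogs are ombrotrophic and Sphagnum-dominated; fens
receive geogenous water, split at pH 5.5 (poor below, rich-intermediate at
or above) or, lacking pH, by peat-moss vs true-moss dominance in the
vegetation notes. When hydrology is geogenous and pH is present, pH decides
— a recorded pH is the more quantitative evidence.

**Pooling.** Years are averaged first within each (study, microform) entry;
microforms remain separate entries because within-peatland surface elements
(hummock/hollow/lawn/pool) have systematically different fluxes and the
spread between them is real variability, not noise. Then per
(ecozone, class, gas): mean, SE = sample sd / √n, n = entries. n = 1 leaves
SE undefined for gap-filling.

**Gap-filling.** Cells with no mean, or no SE, borrow from the most similar
ecozone. The similarity map is explicit configuration keyed by
(ecozone, class, gas) — gas-resolved because the compiled data themselves
borrow the Hudson Plains poor-fen NEE and CH4 cells from *different* donors
(Mixedwood Plains and Boreal Shield respectively). Chained donors (a donor
that is itself gap-filled) resolve over repeated passes; an unresolvable
cell raises with the offending cell list.

## Growing season

Start: the first day at or after March 1 (Julian 60, 365-day calendar) that
opens a 5-consecutive-day run of daily mean ≥ 5 °C; the run must begin
before August 1. End: the first day at or after August 1 (Julian 213) with a
daily minimum < −2 °C. Length = end − start (end-exclusive). The start
indexes the *first* day of the qualifying run; leap days are ignored. Mean
length per ecozone feeds harmonization and upscaling. Where no per-ecozone
value is available the configurable default of **165 days** is used — a
representative mid-boreal length consistent with the worked conversions in
the package tests.

## Peatland map

Nine classes: {open, treed, forested} × {bog, poor fen, rich fen}; codes
1–9 in cover-major order, 0 upland, 10 water, 255 nodata (the explicit
ordering pins down the resampling tie-break and file I/O).

Per-pixel rule precedence:

1. water mask → water;
2. treed/forested-peatland probability ≥ 0.5 → peatland, cover class from
   canopy-closure bins (open < 10%, treed 10–50%, forested ≥ 50%);
3. otherwise, an open-wetland landcover code → open peatland (the landcover
   product contributes only open, < 10%-canopy wetland evidence, so it is
   consulted solely below the probability threshold and always yields the
   open cover class);
4. otherwise upland. NaN in a required layer → nodata.

Nutrient class from tamarack biomass fraction: bog [0, 0.10), poor fen
[0.10, 0.25], rich fen (0.25, 1] — tamarack rises along the bog → rich fen
gradient, and the 10% bog margin absorbs prediction uncertainty in the
source forest-composition layer. The cover bins within probability-detected
peatland are configuration; the probability surface targets treed/forested
peatland, but the bins deliberately include the open class so a
high-probability, low-canopy pixel is not forced into "treed".

Fine (30 m) categorical evidence is coarsened by **majority resampling**:
each factor×factor block takes its modal non-nodata class, ties broken by
the lowest class code (deterministic, documented), all-nodata blocks stay
nodata. Cell area is fixed at 0.0625 km² (250 m cells, equal-area
projection); projection metadata is passed through, not transformed.

Area tables conserve totals exactly (Σ areas = n_cells × cell area) and the
nine → three → two class collapses preserve peatland area exactly.

## Accuracy assessment

Confusion matrices have ground truth in rows and the map in columns.
Overall accuracy = 100 × trace/n; producer's accuracy = diagonal over
column total (omission view); user's = diagonal over row total (commission
view); kappa is standard unweighted Cohen's kappa with zero-margin classes
contributing nothing to expected agreement. Display rounding: percentages
to 0 d.p., kappa to 2 d.p. On the published ground-validation matrix this
yields 37.5% → 38% overall; the published kappa (0.11) does not match the
standard formula on the printed counts (≈ 0.16), so kappa is reported but
not treated as a reproducible quantity.

Polygon comparison bins per-polygon class percentages into 10% intervals
([0,10), …, [90,100]; exactly 100 joins the top bin) and reports the share
of polygons within one bin of the 1:1 line.

## Upscaling and uncertainty

Order of operations: daily EF → seasonal EF per ecozone (× GS/5 for NEE,
× GS/1000 for CH4) → × area (km² → m², g → Mt; Mt = 10¹² g) → sum classes
and ecozones. All steps are linear, so SEs transform by the same factors,
and a full-pipeline property test checks that scaling every EF by c scales
every national total by c.

**SE combination is linear (Σ SE) by default.** The published combined SEs
equal the sums of their per-class components (e.g. 36.4 + 2.2 + 2.7 = 41.3),
so linear addition is required to reproduce them; quadrature (√Σ SE²) is
available as an option and noted in the report footer, since independent
components would normally combine that way.

CH4 → CO2-equivalents by GWP-100 = 25 (configurable). Annualization adds
`winter_rate × (365 − GS_z) × area_z` per ecozone with the winter constants
treated as exact (zero variance) — no winter-flux uncertainty estimate
exists to propagate. The growing-season scenario multiplies seasonal masses
and SEs by the GS scale factor (seasonal totals are linear in GS under the
conversion above); the package validates the ×1.1 scenario against the
arithmetic, not against any absolute baseline.

Budget reports round only at write time (1 d.p. Mt by default) and carry a
footer with the SE rule and winter constants.

## Synthetic data

The generators emulate the study conditions, not real geography:

- **Flux records**: cell means/SDs default to the published separated-fen
  table (SD reconstructed as SE × √n); NEE entries are Gaussian (signed),
  CH4 log-normal with matched mean/SD (fluxes positive and right-skewed).
  Entries become 1–3 yearly records with interannual jitter (10% of cell
  SD), reported on a mixed basis (40/40/20 daily/seasonal/annual) with the
  exact inverse conversions applied — harmonization must undo them.
- **Climate**: a sinusoidal annual cycle peaking on day 200 with 15 °C
  amplitude; the offset is solved so the 5 °C crossings sit the target GS
  apart, and a constant 7 °C mean-to-minimum gap places the first frost at
  the warm-season exit. Zero-noise series hit the target within ±1 day.
- **Landscape**: Gaussian-smoothed random fields rank-mapped to exact
  marginals (piecewise-linear so P(prob ≥ 0.5) equals the configured
  prevalence, default 0.25; tamarack mapped so the within-peatland class mix
  defaults to 70/20/10 bog/poor/rich); Voronoi-block ecozones; smooth-field
  water (2%) and open-wetland evidence (8%); sparse NaN holes exercise the
  nodata path. The oracle map applies the classification rules as plain
  per-pixel nested conditionals, independent of the vectorized builder.
- **Validation points**: sampled on usable cells; labels flipped to a random
  other class with the configured error rate, so expected overall accuracy
  is 100 × (1 − error rate).

All generators are bit-reproducible from their seed. What passing synthetic
tests do **not** show: real peatlands have autocorrelated interannual
climate, non-stationary spatial structure, permafrost features and
observation errors none of which are modeled; agreement here demonstrates
the pipeline's internal correctness, not map accuracy on real layers.

## Known limitations and deliberate choices

- Per-ecozone GS lengths behind the published national totals are
  unpublished; annual totals computed with the 165-day default deviate a few
  percent from the printed annual figures. Seasonal figures reconstruct
  exactly from printed per-class components.
- The winter CO2 constant is 0.9 g m⁻² day⁻¹ throughout (the value used in
  the headline results); 1.0 appears in parts of the source methods text and
  can be set via `Constants(winter_co2=1.0)`.
- Problem sizes in the test-suite and reproduction script (landscapes up to
  500×500 cells, ~10⁴ synthetic records, 100 recovery replicates) are the
  package's chosen desk-scale study conditions; all statistics stabilize
  well below these sizes.
- Swamps, marshes and permafrost peatland classes, regression-tree climate
  analysis, and training of the peatland-probability model are out of scope;
  the probability surface is consumed as an input layer.
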