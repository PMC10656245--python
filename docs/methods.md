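# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `rangecap`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Energy demand

Daily metabolizable energy requirement (MER) of a free-ranging herbivore is
the field-metabolic-rate allometry `ME = a · BM^b / 1000` with `a = 4.82`,
`b = 0.734`, body mass `BM` in grams, `ME` in MJ/day. The law is strictly
increasing and scale-free: doubling body mass multiplies the requirement by
`2^0.734 ≈ 1.66` (a tested invariant).

Body masses are evaluated at the **end of each season**, so energy put into
fat in summer and drawn down over winter is folded into the daily rate.
Published per-species daily requirements for the Pamir herd (e.g. adult
sheep: 11.96 / 14.68 / 10.03 MJ/day in early summer / high summer /
winter) are shipped as the calibration table; the default body masses are
back-derived from them by inverting the allometry, which makes the daily
table reproduce the calibration exactly while remaining overridable with
weighed field data (`SpeciesProfile.body_mass_g`).

The season calendar is the non-leap civil calendar: early summer May–June
(61 d), high summer July–September (92 d), winter October–April (212 d),
totalling 365 (validated by reproducing the published annual MERs: adult
yak 13 789, sheep 4 207, goat 3 798 MJ/yr within ±2 MJ, the rounding of the
printed daily rates). Winter belongs to the preceding growing season:
an early-spring count is booked to the previous calendar year.

Census conventions:

* A plain `summer` census row applies to both growing sub-seasons; cattle
  and camels are present in high summer only, so an annual per-animal
  requirement is undefined for them and requesting one raises an error.
* Winter counts missing in a year are imputed as summer count × the mean
  winter/summer ratio over the reference years with observed winter counts
  (2015–2017 by default), per species with age classes pooled, rounded
  half-up. A per-area refinement would be possible but is off by default;
  the pooled form matches how the historical winter totals were tabulated.
  Imputed historical winters are *not* used as test anchors, because the
  exact pooling used for the published 2013 winter total is not
  recoverable.
* Small livestock units (SLU) = sheep + goat headcount + 3 × (yak + cattle
  + camel). Camels count as large stock — the only convention under which
  all 24 published seasonal totals balance exactly (a tested invariant).

The elevated-requirement scenario multiplies livestock MER by 1.3 for all
species except yak, whose metabolism is assumed adapted to altitude and
cold; wildlife demand is never scaled, as the scenario models stress on
introduced livestock only.

Wildlife: marmots at 16.3 individuals/km² of vegetated land, hibernating
outside May–September; wild ungulates (argali, ibex) year-round. The
marmot hibernation window, the ungulate densities (0.4 and 0.5 /km²) and
all wildlife body masses are **literature-order placeholders, not values
from the calibration source**, and should be replaced with survey data for
any real application. Wildlife demand is distributed over grazing areas in
proportion to their vegetated area, with no accessibility restriction.

## Forage supply

Units: field plots in kg DM/100 m², rasters in kg DM/ha (×100 at the
plot–raster boundary), MEC in MJ/ha/yr.

**Vegetation indices.** Eight indices of the soil-adjusted red/NIR,
red-edge and SWIR families (WDVI, WDVI SA, B8a/B3, NDRE1, NDRE2, MTCI,
SACRI, MSACRI) are computed per pixel from Sentinel-2-style bands. The
bare-soil line (slope α, intercept β) is required configuration with no
default — it is site-specific and must come from a regional soil-line fit.
Division-by-zero pixels become NaN and propagate to prediction nodata.

**Biomass model.** A 500-tree random-forest regressor (scikit-learn
defaults otherwise) maps the 8 indices to standing biomass, with
predictions clamped at zero. Error is characterised by repeated k-fold
*spatial* cross-validation: per repeat, plot coordinates are clustered
into k groups by k-means (repeat-indexed seeds) and each cluster held out
in turn; held-out predictions are pooled into per-repeat metrics (R²,
RMSE, MAE, BIAS and their relative forms as % of the observed mean) and
averaged over repeats. Coordinate clustering was chosen as the blocking
rule because it is deterministic, scale-free and matches standard practice
for spatial CV; the exact blocking used in the calibration source is not
described there.

**Fresh–dry conversion.** Ordinary least squares `dry ~ fresh` for
campaigns that weighed fresh only; degenerate designs (constant fresh
mass, n < 3) are rejected.

**Productivity.** The annual-production / standing-biomass ratio is the
mean over exclosure/grazed pairs of `inside_total / outside_standing`.
Both a global and a per-community pooling are provided; neither is
asserted as the calibration source's choice (only four exclosures survived
there). Zero-denominator pairs are dropped with a warning; a single
surviving pair is accepted but flagged low-confidence.

**MEC assembly.** Per vegetated pixel:
`MEC = max(standing − adjustment, 0) × productivity_ratio ×
consumable_fraction × forage_quality`. Defaults: quality 9.4 MJ/kg DM for
riparian grassland and Salix riparian communities, 9.1 for salt grass and
alpine grassland, 6.3 for dwarf-shrub steppe; consumable fraction 0.5 for
dwarf-shrub steppe (woody biomass), 0.8 elsewhere. No winter quality
reduction is applied (measured seasonal differences were small in the
source data). Non-vegetated classes contribute 0; nodata in any input
propagates. The community-mean internal consistency (production means ×
fraction × quality within 2% of the published community MEC means) is an
acceptance test. The conservative-supply scenario subtracts half the
biomass model's mean MAE (converted to kg DM/ha) from standing biomass
*before* the productivity ratio, because the discount targets the modeled
biomass itself.

## Accessibility

All thresholds use strict `<` ("below"): a pixel at exactly 35% spring
FSC, 78% mean winter FSC or 4500 m is excluded. Rules per season:

* early summer: FSC < 35%, all species, all areas (the threshold is
  applied to the seasonal mean composite);
* high summer: small stock below 4500 m a.s.l.; large stock anywhere
  except winter-use areas, no elevation cap;
* winter: mean Oct–Apr FSC < 78% *and* the area maintains a winter camp.

FSC arrives as pre-aggregated seasonal composites; compositing daily snow
products is upstream of this package. Coarse (500 m) FSC is resampled to
the 10 m grid by nearest neighbour (value-preserving, no interpolation).
Pixels belong to the single polygon containing their center; grazing areas
must not overlap (they are exclusive management units), and catchment
delineation is out of scope — polygons are inputs.

Masks are monotone in their thresholds (tested property), the winter mask
is independent of the DEM, and the high-summer large-stock mask is
independent of FSC.

## Assessment

Annual supply per area counts each pixel's annual MEC **once** if it is
accessible in at least one season, because the balance compares yearly
production to yearly requirements; seasonal sub-accounting is available as
a diagnostic only. Demand from a season in which an area has no
accessible pixels is retained in the area's annual demand (the animals
were counted there) and surfaces as a zero-supply warning.

Utilization = 100 × demand / supply; classification uses strict `>` at
both 40% (unsustainable) and 100% (over-potential), so a rate of exactly
40% is still sustainable. Grazing potential = MEC per ha / annual MER;
carrying capacity = potential × 0.40. Round trips
(`potential × MER = MEC`, `capacity / potential = 0.40`) hold to machine
precision. Region aggregates are computed over vegetated, ever-accessible
pixels; per-area reports round rates to whole percent, potential/capacity
tables to two decimals.

## Synthetic landscape

The generator fabricates the statistical structure the analysis assumes:

* 300 × 300 pixels at 10 m (900 ha) by default — large enough that
  integer herd rounding moves per-area utilization by well under one
  percentage point, small enough that the full chain runs in seconds;
* elevation ramp 3000–6000 m with smooth relief noise; communities
  assigned by elevation rank (riparian valley floor 8%, Salix 5%, salt
  grass 12%, dwarf-shrub steppe 35%, alpine grassland 25%, non-vegetated
  remainder on top);
* per-community annual production drawn around means of 1729 / 1982 /
  641 / 461 / 900 kg DM/ha (SDs ≈ 20%), modulated by a smooth mean-one
  spatial field (±12%); standing biomass = production / 1.4, the
  configured true productivity ratio;
* reflectance bands are linear in scaled biomass plus Gaussian noise
  (SD 0.008 reflectance), so the indices carry a recoverable signal
  (WDVI–biomass correlation > 0.6, tested); soil line α = 1.2, β = 0.04;
* FSC rises with elevation, winter ≈ spring + 35 points, generated at
  500 m and nearest-neighbour resampled;
* grazing areas are west–east strips spanning the full elevation range
  (as real transhumance units do), a configured subset with winter camps;
* the field campaign places 50 / 30 / 30 / 15 stratified plots in
  dwarf-shrub / riparian / alpine / salt-grass communities (the Salix
  shrub community is not clipped, matching the emulated field protocol),
  with 0.3 kg DM/100 m² observation noise; exclosure pairs encode the true
  ratio with 5% scatter; 67 fresh/dry pairs follow a linear law with
  noise chosen to give R² ≈ 0.9;
* the census generator inverts the demand model: integer herds (sheep
  0.40 / goat 0.30 / yak 0.25 / cattle 0.05 of demand, 30% young, winter
  herd 45% of summer in camp areas only) whose annual MER approximates
  target × true accessible supply.

What the generator does **not** emulate: atmospheric effects, cloud gaps,
sensor geometry, within-community species turnover, spatially structured
census error, or snow-depth (vs. cover) limitation. Passing the
closed-loop test therefore shows the estimation chain is internally
consistent and robust to the modeled noise, not that it would meet the
same error on real imagery.

## Numerical choices and problem sizes

* Plot-level noise, band noise and forest size are fixed by
  `LandscapeConfig`; all randomness flows through `numpy.random.default_rng`
  seeded from a single integer, and every generator output is
  bit-reproducible per seed (tested).
* Spatial CV in the self-checks uses 10 repeats of 10 folds (the
  estimator defaults to 100 repeats); 10 repeats already stabilise the
  pooled metrics on the 125-plot campaign to well inside the acceptance
  margins, and keep the check fast.
* K-means blocking uses `n_init=5` and repeat-indexed seeds below 2³¹.
* Imputed counts round half-up; demand always uses integer head counts.
* Rasters are float32 with NaN nodata (uint8 for masks); supply sums are
  accumulated in float64.

## Known limitations

* Wildlife parameters are placeholders (see above).
* The productivity ratio rests on few exclosure pairs in any realistic
  campaign; both pooling modes are offered, and single-pair estimates are
  flagged.
* Grazing-area borders are treated as hard; real herds cross them when
  forage runs short, so strong utilization contrasts across borders are
  partly an artifact of the border model.
* The 5–77% style utilization range depends on whether it is taken over
  areas or pixels; the assessment reports both region aggregates
  (`mean_utilization_pct_areas`, `mean_utilization_pct_pixels`).
* Permanent-snow pixels inside a grazing area are excluded from the
  assessed denominator (never accessible), which slightly shrinks
  area-level denominators relative to total polygon area.
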