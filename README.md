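# rangecap

Carrying-capacity, grazing-potential and utilization-intensity assessment
for cold dryland rangelands.

## The problem

In high-mountain transhumance systems (the package's defaults emulate the
Pamir: yak, sheep, goat, cattle and a few camels moved between spring,
summer and winter pastures at 3000–6000 m), overgrazing is the main driver
of rangeland degradation, but judging whether a grazing area is overused
requires closing an energy balance that most assessments leave incomplete:
how much metabolizable energy the herds *need*, how much the vegetation
*supplies*, and which part of the landscape the animals can actually
*reach* in each season.

`rangecap` implements that balance per grazing area, season, year and
scenario:

* **Demand (MER).** Each animal's daily metabolizable energy requirement
  follows the field-metabolic-rate allometry for free-ranging mammals,
  `ME = 4.82 · BM^0.734 / 1000` (MJ/day, body mass in g), evaluated at
  end-of-season body mass so seasonal fat storage and winter mass loss are
  included. Herd demand is count × daily rate × season length (61 / 92 /
  212 days for early summer / high summer / winter), from census tables
  with adult/young classes, winter-count imputation from summer:winter
  ratios, and herd totals in small livestock units (SLU: sheep + goats +
  3 × large stock). Wild herbivores (marmots at 16.3/km² of vegetated
  land, wild ungulates) enter as an optional scenario; marmot hibernation
  zeroes their winter demand.
* **Supply (MEC).** Standing biomass is mapped from nine multispectral
  reflectance bands through eight vegetation indices (WDVI, soil-adjusted
  WDVI, B8a/B3 ratio, two red-edge NDREs, MTCI, SACRI, MSACRI) and a
  500-tree random-forest regressor trained on clipped field plots,
  validated by repeated coordinate-blocked (spatial) cross-validation.
  Exclosure/grazed pair ratios convert standing biomass to annual
  production; per-community forage quality (9.4 / 9.1 / 6.3 MJ/kg DM) and
  consumable fractions (0.5 for woody dwarf-shrub steppe, 0.8 elsewhere)
  yield the metabolizable energy content in MJ/ha/yr.
* **Accessibility.** Fractional snow cover (FSC) and elevation restrict
  each season: early summer below 35% FSC; high summer below 4500 m for
  small stock while large stock roam everywhere except winter-use areas;
  winter only in areas with winter camps and mean winter FSC below 78%.
* **Assessment.** Utilization intensity = 100 × demand / supply per area;
  grazing potential = MEC per ha / annual MER per animal; carrying
  capacity = potential × 0.40 (the sustainable utilization fraction for
  dry high-mountain rangelands); rates above 40% are classed
  unsustainable, above 100% over-potential. Scenarios: `basic`,
  `mer_plus30` (+30% MER for all livestock except the altitude-adapted
  yak), `conservative_biomass` (standing biomass lowered by half the
  biomass model's mean MAE), `wildlife`, `no_winter`.

Because no public rasters or censuses are distributed for the region the
defaults emulate, the package ships a first-class synthetic-landscape
generator (`rangecap.synthetic`) that fabricates the full input bundle with
known ground truth, so the complete estimation chain can be verified by
closed-loop recovery of configured utilization rates.

## Worked example

```python
import rangecap as rc

profiles = rc.default_species_profiles()
mer_yak = rc.annual_requirement("yak", "adult", profiles)
print(f"adult yak annual MER: {mer_yak:.0f} MJ/yr")
pot = rc.grazing_potential(12967.0, mer_yak)          # riparian MEC, MJ/ha/yr
print(f"riparian grazing potential: {pot:.2f} yak/ha")
print(f"riparian carrying capacity: {rc.carrying_capacity(pot, 0.40):.2f} yak/ha")

from rangecap.pipeline import run_closed_loop
from rangecap.synthetic import LandscapeConfig
res = run_closed_loop(LandscapeConfig(seed=3))        # targets 55/40/25/10 %
print(res.assessed[["area_id", "supply_mj", "demand_livestock_mj",
                    "utilization_pct", "class"]].round(1).to_string(index=False))
```

prints

```
adult yak annual MER: 13788 MJ/yr
riparian grazing potential: 0.94 yak/ha
riparian carrying capacity: 0.38 yak/ha
area_id  supply_mj  demand_livestock_mj  utilization_pct         class
 area_1   702868.9             388094.0             55.2 unsustainable
 area_2   645776.8             262904.7             40.7 unsustainable
 area_3  1084626.7             273106.0             25.2   sustainable
 area_4   744545.7              78751.1             10.6   sustainable
```

One hectare of riparian grassland can feed about one yak for a year at
full exploitation, or 0.38 yak sustainably; the synthetic areas, configured
at 55/40/25/10% utilization, are recovered within about one percentage
point by the full estimation chain (biomass model, productivity ratio,
snow/elevation masks, census demand), and classed against the 40%
threshold.

The same pipeline is available from the shell:

```sh
rangecap simulate --out run1 --seed 7        # write a synthetic input bundle
rangecap assess --config run1/run.yaml       # report.csv, utilization_*.tif
rangecap report --results run1/results
```

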