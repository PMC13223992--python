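# pycfire

Century-scale accounting of **pyrogenic carbon (PyC)** production from
vegetation fires, built as a bottom-up, gridded emission inventory with
decay, trend, and uncertainty analysis.

When biomass burns, most of the consumed carbon is released as CO₂, but a
fraction is converted into char/black carbon — pyrogenic carbon — which
decomposes orders of magnitude more slowly than uncharred organic matter
and so acts as a persistent carbon pool. `pycfire` quantifies annual PyC
production over a 0.5° raster from burned area, plant-functional-type
(PFT) resolved biomass, and soil moisture, then tracks the cumulative PyC
stock through a two-pool decay model, estimates period-wise trends, and
propagates parameter uncertainty by Monte Carlo. It is aimed at
fire-emission and carbon-budget researchers who want a tested, scriptable
implementation of this accounting chain, with a synthetic-data generator
standing in for the large gridded input datasets.

## The model

Per grid cell, PyC production sums over PFTs *i* and fuel categories *j*:

```
PyC = Σᵢ Σⱼ  FLᵢⱼ / DMCCᵢ × BAᵢ × CCⱼ × EFᵢ × 10⁻³ × 12/44 × P_PyCⱼ
```

* **FL** — fuel load (gC m⁻²): leaf, aboveground sapwood, aboveground
  heartwood, and fruit biomass, allocated to 1-h/10-h/100-h/1000-h
  time-lag classes (woody mass split 4.5/7.5/21/67%) and grouped into
  non-wood (NWF), fine-wood (FWF) and coarse-wood (CWF) fuel categories.
* **BA** — burned area (m²), ingested as burned fraction per land-cover
  class (forest / non-forest) and partitioned among PFTs by fractional
  cover.
* **CC** — combustion completeness per fuel category, scaled linearly
  with soil moisture between each cell's 5th and 95th percentile (drier
  → more complete combustion by default).
* **EF**, **DMCC** — CO₂ emission factor (g CO₂ kg⁻¹ dry matter) and
  dry-matter carbon fraction, by bioclimatic class
  (tropical/temperate/boreal/savanna); 10⁻³ bridges g→kg dry matter and
  12/44 converts CO₂ to carbon mass.
* **P_PyC** — fuel-category-specific PyC:CO₂-C production factor.

The cumulative stock applies the two-pool decay curve
`PyC_remain(t) = a·e^(−k_l t) + b·e^(−k_s t)` (labile a = 9.1%,
k_l = 0.5 yr⁻¹; stable b = 90.9%, k_s = 1.1×10⁻³ yr⁻¹) to every past
year's production. Trends are OLS fits over prescribed periods with a
two-sided t-test (break year 2004 by default, included in both periods);
uncertainty is a 1000-iteration Monte Carlo over independent normal
parameter draws, reported as the 2.5/97.5 percentile envelope.

## Worked example

```python
from pycfire import (ScenarioConfig, generate_scenario, run_inventory,
                     pyc_co2_ratio, aggregate_regional, regional_shares,
                     cumulative_stock, piecewise_trends)

bundle, grid, taxonomy = generate_scenario(ScenarioConfig(seed=1))
result = run_inventory(bundle, grid, taxonomy)

forest = result.national_pyc_tgc("forest")
print(f"forest mean PyC: {forest.mean():.3f} TgC/yr")
print(f"forest PyC:CO2: {pyc_co2_ratio(result)['forest'].mean():.3f}")
shares = regional_shares(aggregate_regional(result, grid), "forest")
print(f"Northeast share: {shares['Northeast']:.3f}")
print(f"2020 stock: {cumulative_stock(forest).loc[2020, 'stock']:.1f} TgC")
pre, post = piecewise_trends(forest, 2004)
print(f"slopes: {pre.slope:+.4f} / {post.slope:+.4f} TgC/yr^2")
```

prints

```
forest mean PyC: 1.287 TgC/yr
forest PyC:CO2: 0.205
Northeast share: 0.788
2020 stock: 132.8 TgC
slopes: +0.0122 / -0.0821 TgC/yr^2
```

i.e. on this synthetic scenario about 1.3 TgC of PyC forms per year in
forest fires — roughly 20% of the associated CO₂-C flux, the weighted
mean of the fuel-category production factors — with the hotspot region
holding ~79% of production; 132.8 TgC of the century's production remains
in 2020 after decay, and the national series rises to 2004 and declines
after it (both slopes significant at p < 0.05).

The same pipeline runs from a shell:

```bash
pycfire run --config my_run.yaml --out results/
pycfire synth --seed 7 bundle.nc        # write a synthetic input bundle
pycfire trends results/national_series.csv --break-year 2004
```

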