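# Methods

## Accounting chain

`pycfire` implements a bottom-up fire-emission inventory specialised for
pyrogenic carbon (PyC). The chain, in execution order:

1. **Grid and inputs.** All fields live on a regular 0.5° cell-centered
   lat/lon raster (latitude ascending) with exact spherical cell areas
   (R = 6 371 000 m) and an integer mask partitioning the active domain
   into seven subregions (region 1 is the "Northeast" hotspot). Burned
   area enters as burned *fraction* of cell per land-cover class
   (forest / non-forest) — resolution-independent and matching how
   reconstructed products ship — and is converted to m² internally.
   Monthly fields, if supplied, are summed to annual before any
   computation. Ten natural PFTs are carried (8 forest, 2 grass); managed
   classes are out of scope.
2. **Fuels.** Aboveground biomass components (leaf, aboveground sapwood,
   aboveground heartwood, fruit; belowground pools are ignored with a
   warning) are allocated to time-lag classes — leaves and fruit entirely
   to 1-h; sapwood/heartwood split 4.5% / 7.5% / 21% / 67% across
   1-h/10-h/100-h/1000-h — then grouped into fuel categories
   NWF = 1-h, FWF = 10-h + 100-h, CWF = 1000-h. Both steps conserve mass
   exactly; tests assert ≤1e-9 relative. Burned area per land-cover
   class is partitioned among that class's PFTs in proportion to
   fractional cover (cover share within the class, since forest and
   non-forest burned areas are supplied separately). Cells burning with
   zero class cover contribute nothing; the dropped area is logged.
3. **Combustion completeness.** CC is bounded per fuel category
   (defaults NWF 0.70–1.00, FWF 0.40–0.70, CWF 0.20–0.50) and scaled
   linearly with soil moisture between each cell's 5th and 95th
   percentile (linear interpolation between order statistics, computed
   per cell over the full record by default; a pooled mode exists).
   Default direction is `dry_max` — soil moisture at or below the 5th
   percentile maps to cc_max, i.e. drier fuels burn more completely,
   the GFED-style convention — with `wet_max` available as the mirror
   reading; the two reflect about the CC midpoint. Cells with a
   degenerate (constant) moisture record fall back to the midpoint CC.
4. **Inventory.** Per cell, PFT *i*, category *j*:
   `CO2-C = FL/DMCC × BA × CC × EF × 1e-3 × 12/44` (gC) and
   `PyC = CO2-C × P_PyC_j`. The explicit 1e-3 converts grams of dry
   matter to kilograms to match EF units — the equation as usually
   written leaves this bridge implicit. Fuel categories are nested
   within PFTs, so the double sum counts nothing twice. Accumulation
   stays in gC; conversion to TgC happens only at reporting. Forest and
   non-forest totals are kept separate end to end. The run loops one
   year at a time over a vectorized (PFT × category × lat × lon) kernel,
   bounding memory at a few MB for a 20×20 grid.
5. **Ratios, regions, decay, trends.** The national PyC:CO₂-C ratio is
   the production-weighted mean of the category factors (undefined and
   reported missing in zero-fire years). Regional series are masked
   sums; they partition the national total by construction. Cumulative
   stocks convolve annual production with the two-pool decay curve
   `a·e^(−k_l t) + b·e^(−k_s t)` (a = 9.1%, b = 90.9%, k_l = 0.5 yr⁻¹,
   k_s = 1.1e-3 yr⁻¹); production is treated as arriving at the start of
   its year (lag-0 factor exactly 1), with no sub-annual decay
   convention. Trends are OLS on year (centered before fitting for
   conditioning; slope unchanged) with the two-sided t-test p-value and
   a p < 0.05 significance rule; breakpoints are configuration, not
   detected, default 2004 and included in both sub-periods. Quartiles
   use linear interpolation; sd uses the n−1 denominator.

## Parameter defaults

The shipped CSV pack (`src/pycfire/data/`) holds representative values
for the GFED-style parameter classes; **every value is a config
override** because these quantities are dataset-specific:

| parameter | default | units |
|---|---|---|
| EF CO₂ (tropical/temperate/boreal/savanna) | 1643 / 1647 / 1489 / 1686 | g CO₂ kg⁻¹ DM |
| DMCC (same classes) | 0.49 / 0.47 / 0.45 / 0.45 | fraction |
| CC bounds (NWF/FWF/CWF) | 0.70–1.00 / 0.40–0.70 / 0.20–0.50 | fraction |
| P_PyC mean (NWF/FWF/CWF) | 0.110 / 0.170 / 0.260 | PyC : CO₂-C |
| P_PyC 95% CI | 0.07–0.15 / 0.10–0.24 / 0.18–0.34 | — |

P_PyC rises from fine to coarse fuels: coarse wood chars rather than
oxidising, so CWF dominates PyC formation where stem biomass burns.
Grass PFTs take the savanna parameter class. Decay constants as above.

## Uncertainty and sensitivity

The inventory is linear in fuel load, EF, CC and P_PyC, and inversely
linear in DMCC. Both analyses therefore rescale the base run's national
(year × land-cover × PFT × category) decomposition instead of re-running
the grid: a parameter draw multiplies its terms by `draw/mean`
(`mean/draw` for DMCC). The rescaling is exact, not an approximation,
and makes the documented P_PyC_j ≡ CC_j sensitivity equivalence hold to
machine precision — which also means CC perturbations are deliberately
**not** re-clipped to the category bounds.

Monte Carlo: one value per parameter per iteration, shared across all
cells and years (parameter error is systematic; per-cell independence
would artificially shrink national CIs), independent across parameters
(no covariance information exists for these tables). Draws outside the
physical bounds are redrawn, up to 100 attempts, rather than truncated.
1000 iterations by default; the envelope is the empirical 2.5/97.5
percentile band. The run is reproducible under a single seed via spawned
per-iteration substreams. Default spreads: fuel-load scale CV 18%
(multi-model biomass spread), P_PyC sd from the table CIs, EF CV 10% and
DMCC CV 5% as placeholder magnitudes to be overridden when better
constraints exist.

Sensitivity perturbs 13 targets one at a time (fuel load; P_PyC and CC
per category; DMCC and EF per forest bioclimatic class) by −10%, −5%,
+5%, +10%, reporting ΔPyC per year plus a mean-annual summary table.
Multiplicative parameters respond by exactly the perturbation fraction
on their terms; DMCC by 1/(1+δ) − 1.

## Synthetic scenarios

The generator produces complete input bundles with the structure the
analysis assumes, so the whole chain is testable without downloads:

* **Burned fraction**: piecewise-linear national mean (default forest
  2.0e-3 rising by 4.0e-5 yr⁻¹ to a 2004 break, then falling by
  2.5e-4 yr⁻¹ — a sharp post-break decline of the kind a
  fire-suppression era produces; non-forest analogous at lower levels),
  modulated by a shared lognormal interannual factor (CV 0.10 default),
  per-cell lognormal noise (CV 0.30), Bernoulli burn occurrence (0.70),
  and a spatial weight field that places a target share (default 0.79)
  of burned area in the hotspot region; clipped to [0, 1] after noise.
* **Biomass**: static per-PFT component means (forest ≈ 5.8 kgC m⁻²
  aboveground with woody mass dominant; grass ≈ 0.16 kgC m⁻², no woody
  components) with a fixed spatial lognormal pattern (CV 0.20).
* **Soil moisture**: per-cell AR(1) (mean 0.30, sd 0.05, ρ 0.6), which
  makes the percentile-based CC scaling meaningful.
* **PFT cover**: forest-dominant hotspot (0.75 vs 0.35 elsewhere),
  boreal PFTs weighted toward high latitude, grass cover 0.20.
* Regions are axis-aligned rectangles; geometry is irrelevant to the
  computation.

Everything is deterministic under the configured seed. An impulse
generator produces single-cell, single-year fires for oracle and
impulse-response tests.

What passing tests show — and don't. The synthetic fields reproduce the
*structural* properties the method relies on (sparsity, hotspot
concentration, a trend break, moisture variability, component-resolved
biomass), so the tests establish correctness of the accounting
arithmetic, conservation, calibration of the Monte Carlo, and
recoverability of prescribed trends. They do not emulate real fire-size
distributions, fire–climate covariance, biomass dynamics, or observation
error in a reconstructed burned-area product, so absolute magnitudes
from synthetic runs are not estimates of any real region's PyC budget.

## Numerical choices and edge cases

* Percentiles/quartiles: linear interpolation between order statistics
  throughout.
* Degenerate inputs: constant soil-moisture series → midpoint CC;
  zero-fire year → missing ratio; burned area with zero class cover →
  dropped with a logged count; zero-variance trend series → slope 0,
  p = 1; single-value descriptives → sd missing.
* Validation rejects negative masses/areas/fractions, burned fraction
  > 1, per-cell cover sums > 1, non-contiguous year axes, region labels
  outside 0–7, and DMCC outside (0, 1).
* NetCDF IO uses xarray's scipy backend (NetCDF3 classic); label axes
  are encoded as integer indices plus a label attribute, round-tripping
  float64 bit-exactly.
* Default problem sizes (20×20 cells × 120 years; 1000 MC iterations)
  run the full pipeline in about a second on one CPU; larger domains
  scale linearly in cells and years.

## Known limitations

Fixed allocation fractions in space and time; cover-proportional fire
susceptibility; a linear (no non-linear extreme-moisture) CC response;
no trace gases other than CO₂; no fire seasonality; no peatland,
cropland or pasture classes; no reburning or temperature modulation of
decay; national/regional stocks only (no gridded stock fields); no
parameter covariance and no variance-based (Sobol) sensitivity.
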