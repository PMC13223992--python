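"""Bottom-up PyC production inventory.

Per grid cell, PFT *i* and fuel category *j*::

    CO2-C_ij = FL_ij / DMCC_i × BA_i × CC_j × EF_i × 1e-3 × 12/44   [gC]
    PyC_ij   = CO2-C_ij × P_PyC_j                                    [gC]

where FL is fuel load (gC m⁻²), BA burned area (m²), CC combustion
completeness, EF the CO2 emission factor (g CO2 per kg dry matter), DMCC
the carbon fraction of dry matter, and P_PyC the fuel-category-specific
PyC:CO2-C production factor. The 1e-3 bridges the g→kg dry-matter unit
between FL/DMCC·BA (g DM) and EF (per kg DM); 12/44 converts CO2 mass to
carbon mass.

Fuel categories are nested within PFTs, so summing every (PFT, category)
term counts nothing twice. Accumulation stays in gC; conversion to TgC
happens only at reporting. Forest and non-forest inventories are carried
separately end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .combustion import (
    CombustionParams,
    PyCFactorTable,
    lookup_pft_params,
    scale_cc,
    soil_moisture_percentiles,
)
from .fuels import AllocationScheme, fuel_load_by_category, partition_burned_area
from .grid_core import (
    FUEL_CATEGORIES,
    LANDCOVERS,
    N_REGIONS,
    REGION_NAMES,
    FuelTaxonomy,
    GridDomain,
    GridError,
    InputBundle,
    PFTTaxonomy,
    burned_fraction_to_area,
)

GC_PER_TGC = 1e12
CO2_TO_C = 12.0 / 44.0
G_TO_KG = 1e-3


def compute_cell_emissions(fl, ba, cc, ef, dmcc, p_pyc):
    """Eq.-level emission arithmetic; broadcasts over numpy inputs.

    Returns ``(co2_c, pyc)`` in gC. ``fl`` in gC m⁻², ``ba`` in m²,
    ``ef`` in g CO2 kg⁻¹ DM, ``cc``/``dmcc``/``p_pyc`` dimensionless.
    """
    fl, ba, cc, ef, dmcc, p_pyc = map(np.asarray, (fl, ba, cc, ef, dmcc, p_pyc))
    if np.any(dmcc <= 0):
        raise ZeroDivisionError("DMCC must be positive to convert carbon to dry matter")
    for name, arr in (("fl", fl), ("ba", ba), ("cc", cc), ("ef", ef), ("p_pyc", p_pyc)):
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(f"{name} must be finite and non-negative")
    co2_c = (fl / dmcc) * ba * cc * ef * G_TO_KG * CO2_TO_C
    return co2_c, co2_c * p_pyc


@dataclass
class PyCResult:
    """Inventory output: gridded totals plus the national decomposition.

    ``co2c_national`` / ``pyc_national`` carry the full ``(year,
    landcover, pft, fuel_category)`` national sums in gC — the exact
    linear decomposition that uncertainty propagation rescales.
    ``co2c_grid`` / ``pyc_grid`` are ``(year, landcover, lat, lon)`` gC.
    """

    co2c_grid: xr.DataArray
    pyc_grid: xr.DataArray
    co2c_national: xr.DataArray
    pyc_national: xr.DataArray
    p_pyc: dict[str, float]

    @property
    def years(self) -> np.ndarray:
        return self.pyc_grid.coords["year"].values

    def national_pyc_tgc(self, landcover: str | None = None) -> pd.Series:
        """Annual national PyC production in TgC yr⁻¹."""
        da = self.pyc_national
        da = da.sel(landcover=landcover) if landcover else da.sum("landcover")
        vals = da.sum([d for d in da.dims if d != "year"]).values / GC_PER_TGC
        return pd.Series(vals, index=self.years, name="pyc_tgc")

    def national_co2c_tgc(self, landcover: str | None = None) -> pd.Series:
        da = self.co2c_national
        da = da.sel(landcover=landcover) if landcover else da.sum("landcover")
        vals = da.sum([d for d in da.dims if d != "year"]).values / GC_PER_TGC
        return pd.Series(vals, index=self.years, name="co2c_tgc")

    def pyc_by_category_tgc(self, landcover: str) -> pd.DataFrame:
        """Annual national PyC split by fuel category, TgC yr⁻¹."""
        da = self.pyc_national.sel(landcover=landcover).sum("pft") / GC_PER_TGC
        return pd.DataFrame(da.values, index=self.years, columns=list(FUEL_CATEGORIES))


def run_inventory(
    bundle: InputBundle,
    grid: GridDomain,
    pft_taxonomy: PFTTaxonomy,
    fuel_taxonomy: FuelTaxonomy | None = None,
    params: CombustionParams | None = None,
    pyc_factors: PyCFactorTable | None = None,
    scheme: AllocationScheme | None = None,
    cc_direction: str = "dry_max",
    percentile_mode: str = "per_cell",
    grass_all_nwf: bool = False,
) -> PyCResult:
    """Run the full gridded inventory over every year, cell, PFT and category."""
    fuel_taxonomy = fuel_taxonomy or FuelTaxonomy()
    params = params or CombustionParams.default()
    pyc_factors = pyc_factors or PyCFactorTable.default()
    bundle.validate(grid)

    pfts = bundle.pfts
    years = bundle.years
    nlat, nlon = grid.shape

    # stage 1: burned fraction -> m², partitioned among PFTs by cover
    ba_lc = burned_fraction_to_area(bundle, grid)
    ba_pft = partition_burned_area(ba_lc, bundle.pft_cover, pft_taxonomy)

    # stage 2: fuel loads per category (gC m⁻²)
    fl = fuel_load_by_category(
        bundle.biomass, scheme, fuel_taxonomy, pft_taxonomy, grass_all_nwf
    )

    # stage 3: moisture-scaled combustion completeness per category
    bounds = soil_moisture_percentiles(bundle.soil_moisture, mode=percentile_mode)[:2]
    cc = scale_cc(bundle.soil_moisture, bounds, params, cc_direction)

    # stage 4: per-PFT parameter vectors
    ef = np.array([lookup_pft_params(p, pft_taxonomy, params)[0] for p in pfts])
    dmcc = np.array([lookup_pft_params(p, pft_taxonomy, params)[1] for p in pfts])
    ppyc = np.array([pyc_factors.p_pyc[c] for c in FUEL_CATEGORIES])
    lc_of = np.array([pft_taxonomy.landcover[p] for p in pfts])

    fl_v = fl.transpose("year", "pft", "fuel_category", "lat", "lon").values
    ba_v = ba_pft.transpose("year", "pft", "lat", "lon").values
    cc_v = cc.transpose("year", "fuel_category", "lat", "lon").values

    co2c_grid = np.zeros((len(years), len(LANDCOVERS), nlat, nlon))
    pyc_grid = np.zeros_like(co2c_grid)
    co2c_nat = np.zeros((len(years), len(LANDCOVERS), len(pfts), len(FUEL_CATEGORIES)))
    pyc_nat = np.zeros_like(co2c_nat)

    scale = G_TO_KG * CO2_TO_C
    for iy in range(len(years)):  # one year at a time to bound memory
        # (pft, cat, lat, lon)
        co2c = (
            (fl_v[iy] / dmcc[:, None, None, None])
            * ba_v[iy][:, None, :, :]
            * cc_v[iy][None, :, :, :]
            * ef[:, None, None, None]
            * scale
        )
        pyc = co2c * ppyc[None, :, None, None]
        for il, lc in enumerate(LANDCOVERS):
            sel = lc_of == lc
            co2c_grid[iy, il] = co2c[sel].sum(axis=(0, 1))
            pyc_grid[iy, il] = pyc[sel].sum(axis=(0, 1))
            co2c_nat[iy, il][sel] = co2c[sel].sum(axis=(2, 3))
            pyc_nat[iy, il][sel] = pyc[sel].sum(axis=(2, 3))

    grid_coords = {
        "year": years,
        "landcover": list(LANDCOVERS),
        "lat": grid.lat_centers,
        "lon": grid.lon_centers,
    }
    nat_coords = {
        "year": years,
        "landcover": list(LANDCOVERS),
        "pft": pfts,
        "fuel_category": list(FUEL_CATEGORIES),
    }
    gdims = ("year", "landcover", "lat", "lon")
    ndims = ("year", "landcover", "pft", "fuel_category")
    return PyCResult(
        co2c_grid=xr.DataArray(co2c_grid, coords=grid_coords, dims=gdims, attrs={"units": "gC"}),
        pyc_grid=xr.DataArray(pyc_grid, coords=grid_coords, dims=gdims, attrs={"units": "gC"}),
        co2c_national=xr.DataArray(co2c_nat, coords=nat_coords, dims=ndims, attrs={"units": "gC"}),
        pyc_national=xr.DataArray(pyc_nat, coords=nat_coords, dims=ndims, attrs={"units": "gC"}),
        p_pyc=dict(pyc_factors.p_pyc),
    )


def aggregate_regional(result: PyCResult, grid: GridDomain) -> xr.DataArray:
    """Sum gridded PyC into the seven subregions; TgC yr⁻¹ per land cover.

    Regional sums partition the national total because every active cell
    carries exactly one region label.
    """
    if result.pyc_grid.sizes["lat"] != grid.shape[0] or result.pyc_grid.sizes["lon"] != grid.shape[1]:
        raise GridError("result grid does not match the domain")
    layers = []
    for region in range(1, N_REGIONS + 1):
        mask = xr.DataArray(
            grid.region_mask(region),
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
            dims=("lat", "lon"),
        )
        layers.append(result.pyc_grid.where(mask, 0.0).sum(("lat", "lon")) / GC_PER_TGC)
    out = xr.concat(layers, dim="region").assign_coords(region=np.arange(1, N_REGIONS + 1))
    out = out.transpose("year", "landcover", "region")
    out.attrs["units"] = "TgC yr-1"
    out.attrs["region_names"] = ",".join(REGION_NAMES[r] for r in range(1, N_REGIONS + 1))
    return out


def regional_shares(regional: xr.DataArray, landcover: str) -> pd.Series:
    """Mean-annual regional share of the national total (fractions)."""
    mean = regional.sel(landcover=landcover).mean("year")
    total = float(mean.sum())
    if total <= 0:
        raise ValueError(f"no {landcover} production to apportion")
    return pd.Series(
        (mean / total).values,
        index=[REGION_NAMES[r] for r in range(1, N_REGIONS + 1)],
        name="share",
    )


def pyc_co2_ratio(result: PyCResult) -> pd.DataFrame:
    """Annual national PyC : CO2-C ratio per land-cover class.

    A production-weighted mean of the fuel-category P_PyC values, so it
    is bounded by the extreme factors whenever CO2-C > 0. Zero-fire years
    are reported as missing (NaN).
    """
    out = {}
    for lc in LANDCOVERS:
        pyc = result.national_pyc_tgc(lc)
        co2 = result.national_co2c_tgc(lc)
        ratio = pyc / co2.where(co2 > 0)
        out[lc] = ratio
    return pd.DataFrame(out, index=result.years)
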