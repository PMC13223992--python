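"""Spatial and taxonomic data model shared by every pipeline stage.

The pipeline operates on a regular 0.5° latitude/longitude raster over a
China-like domain partitioned into seven subregions (Northeast, East,
Central, North, South, Northwest, Southwest). All gridded inputs — burned
fraction per land-cover class, biomass per plant functional type (PFT) and
component, soil moisture, PFT fractional cover — share one
:class:`GridDomain` and one integer year axis, and are carried as
:class:`xarray.DataArray` objects with named dimensions.

Conventions (asserted at load):

* cell-center registration, latitude stored ascending;
* year axis is integer calendar years;
* burned area is ingested as burned *fraction* of cell per land-cover
  class and converted to m² internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger("pycfire")

# -- module-wide constants ---------------------------------------------------

EARTH_RADIUS_M = 6_371_000.0
GRID_STEP_DEG = 0.5

#: Land-cover classes carried separately end-to-end.
LANDCOVERS = ("forest", "nonforest")

#: Region labels: 0 = outside domain, 1..7 = subregions.
N_REGIONS = 7
REGION_NAMES = {
    0: "outside",
    1: "Northeast",
    2: "East",
    3: "Central",
    4: "North",
    5: "South",
    6: "Northwest",
    7: "Southwest",
}

#: Aboveground biomass components accepted as fuel.
COMPONENTS = ("leaf", "aboveground_sapwood", "aboveground_heartwood", "fruit")

#: Time-lag fuel classes (moisture-equilibration timescale of stems).
TIMELAG_CLASSES = ("1h", "10h", "100h", "1000h")

#: Fuel categories used by the PyC production factors.
FUEL_CATEGORIES = ("NWF", "FWF", "CWF")

#: Time-lag class -> fuel category (1-h fuels are non-wood, 10-h and 100-h
#: fine wood, 1000-h coarse wood).
CATEGORY_OF_TIMELAG = {"1h": "NWF", "10h": "FWF", "100h": "FWF", "1000h": "CWF"}

BIOCLIMATIC_CLASSES = ("tropical", "temperate", "boreal", "savanna")


class GridError(ValueError):
    """Raised for malformed grids, masks, or mismatched field shapes."""


class ValidationError(ValueError):
    """Raised when an input field violates a physical invariant."""


# -- grid --------------------------------------------------------------------


@dataclass(frozen=True)
class GridDomain:
    """A regular 0.5° raster with cell areas and a seven-region mask.

    Attributes
    ----------
    lat_centers, lon_centers
        Cell-center coordinates in degrees; latitude ascending.
    cell_area
        Cell area in m², shape ``(nlat, nlon)``; varies only with latitude.
    region_id
        Integer label per cell in ``{0..7}`` (0 = outside the domain).
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_area: np.ndarray
    region_id: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_area.shape != self.shape or self.region_id.shape != self.shape:
            raise GridError(
                f"cell_area/region_id shape must be {self.shape}, got "
                f"{self.cell_area.shape} / {self.region_id.shape}"
            )
        if not np.all(self.cell_area > 0):
            raise GridError("all cell areas must be positive")
        bad = set(np.unique(self.region_id)) - set(range(N_REGIONS + 1))
        if bad:
            raise GridError(f"region_id labels outside 0..{N_REGIONS}: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lat_centers), len(self.lon_centers)

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def region_mask(self, region: int) -> np.ndarray:
        """Boolean mask of cells belonging to ``region``."""
        return self.region_id == region

    def spatial_coords(self) -> dict[str, np.ndarray]:
        return {"lat": self.lat_centers, "lon": self.lon_centers}


def _cell_band_area(lat_center: np.ndarray, dlat: float, dlon: float) -> np.ndarray:
    """Exact area of a spherical quadrilateral cell centered at ``lat_center``."""
    lat_s = np.deg2rad(lat_center - dlat / 2.0)
    lat_n = np.deg2rad(lat_center + dlat / 2.0)
    return EARTH_RADIUS_M**2 * np.deg2rad(dlon) * (np.sin(lat_n) - np.sin(lat_s))


def build_grid(
    lat_bounds: tuple[float, float],
    lon_bounds: tuple[float, float],
    region_mask_source: np.ndarray,
) -> GridDomain:
    """Construct a :class:`GridDomain` at 0.5° from outer bounds and a mask.

    Parameters
    ----------
    lat_bounds, lon_bounds
        Outer edges ``(south, north)`` / ``(west, east)`` in degrees; the
        span must be a positive multiple of 0.5°.
    region_mask_source
        Integer labels per cell, shape ``(nlat, nlon)`` with latitude
        ascending along axis 0.
    """
    step = GRID_STEP_DEG
    nlat = (lat_bounds[1] - lat_bounds[0]) / step
    nlon = (lon_bounds[1] - lon_bounds[0]) / step
    if nlat <= 0 or nlon <= 0 or abs(nlat - round(nlat)) > 1e-9 or abs(nlon - round(nlon)) > 1e-9:
        raise GridError(
            f"bounds {lat_bounds}/{lon_bounds} do not define a nonempty raster at {step}° step"
        )
    nlat, nlon = int(round(nlat)), int(round(nlon))
    lat = lat_bounds[0] + step / 2.0 + step * np.arange(nlat)
    lon = lon_bounds[0] + step / 2.0 + step * np.arange(nlon)

    mask = np.asarray(region_mask_source, dtype=np.int64)
    if mask.shape != (nlat, nlon):
        raise GridError(f"region mask shape {mask.shape} does not match raster {(nlat, nlon)}")

    band = _cell_band_area(lat, step, step)
    cell_area = np.broadcast_to(band[:, None], (nlat, nlon)).copy()
    return GridDomain(lat_centers=lat, lon_centers=lon, cell_area=cell_area, region_id=mask)


def region_mask_from_csv(path, grid_shape: tuple[int, int], lat, lon) -> np.ndarray:
    """Read a ``(lat, lon, region)`` CSV into a dense integer mask."""
    df = pd.read_csv(path)
    mask = np.zeros(grid_shape, dtype=np.int64)
    ilat = {round(float(v), 4): i for i, v in enumerate(lat)}
    ilon = {round(float(v), 4): i for i, v in enumerate(lon)}
    for _, row in df.iterrows():
        try:
            mask[ilat[round(float(row["lat"]), 4)], ilon[round(float(row["lon"]), 4)]] = int(
                row["region"]
            )
        except KeyError as exc:
            raise GridError(f"region CSV coordinate {exc} not on the grid") from exc
    return mask


# -- taxonomies --------------------------------------------------------------


@dataclass(frozen=True)
class PFTTaxonomy:
    """Plant functional types with land-cover and bioclimatic class mapping."""

    pft_ids: tuple[str, ...]
    landcover: dict[str, str]  # pft -> forest | nonforest
    bioclimatic_class: dict[str, str]  # pft -> tropical | temperate | boreal | savanna

    def __post_init__(self) -> None:
        for pft in self.pft_ids:
            if pft not in self.landcover or pft not in self.bioclimatic_class:
                raise GridError(f"PFT {pft!r} missing a land-cover or bioclimatic class")
            if self.landcover[pft] not in LANDCOVERS:
                raise GridError(f"PFT {pft!r}: unknown land cover {self.landcover[pft]!r}")
            if self.bioclimatic_class[pft] not in BIOCLIMATIC_CLASSES:
                raise GridError(
                    f"PFT {pft!r}: unknown bioclimatic class {self.bioclimatic_class[pft]!r}"
                )

    def pfts_of_landcover(self, lc: str) -> tuple[str, ...]:
        return tuple(p for p in self.pft_ids if self.landcover[p] == lc)

    @property
    def forest_pfts(self) -> tuple[str, ...]:
        return self.pfts_of_landcover("forest")

    @property
    def nonforest_pfts(self) -> tuple[str, ...]:
        return self.pfts_of_landcover("nonforest")


def default_pft_taxonomy() -> PFTTaxonomy:
    """Eight natural forest PFTs plus C3/C4 natural grass.

    Managed classes (cropland, pasture) are excluded upstream; grass PFTs
    take the savanna/grassland parameter class.
    """
    forest = {
        "TrBE": "tropical",  # tropical broadleaf evergreen
        "TrBR": "tropical",  # tropical broadleaf raingreen
        "TeNE": "temperate",  # temperate needleleaf evergreen
        "TeBE": "temperate",  # temperate broadleaf evergreen
        "TeBS": "temperate",  # temperate broadleaf summergreen
        "BoNE": "boreal",  # boreal needleleaf evergreen
        "BoBS": "boreal",  # boreal broadleaf summergreen
        "BoNS": "boreal",  # boreal needleleaf summergreen
    }
    grass = {"C3G": "savanna", "C4G": "savanna"}
    pfts = tuple(forest) + tuple(grass)
    landcover = {p: "forest" for p in forest} | {p: "nonforest" for p in grass}
    return PFTTaxonomy(
        pft_ids=pfts, landcover=landcover, bioclimatic_class={**forest, **grass}
    )


@dataclass(frozen=True)
class FuelTaxonomy:
    """Biomass components, time-lag classes and their fuel-category grouping."""

    components: tuple[str, ...] = COMPONENTS
    timelag_classes: tuple[str, ...] = TIMELAG_CLASSES
    fuel_categories: tuple[str, ...] = FUEL_CATEGORIES
    category_of_timelag: dict[str, str] = field(
        default_factory=lambda: dict(CATEGORY_OF_TIMELAG)
    )

    def __post_init__(self) -> None:
        if set(self.category_of_timelag) != set(self.timelag_classes):
            raise GridError("category_of_timelag must map every time-lag class")
        if set(self.category_of_timelag.values()) != set(self.fuel_categories):
            raise GridError("category_of_timelag must be surjective onto the fuel categories")

    def timelags_of_category(self, cat: str) -> tuple[str, ...]:
        return tuple(t for t in self.timelag_classes if self.category_of_timelag[t] == cat)


# -- input bundle ------------------------------------------------------------


@dataclass
class InputBundle:
    """One scenario's full gridded input set on a shared grid and year axis.

    Attributes
    ----------
    burned_fraction
        ``(year, landcover, lat, lon)`` burned fraction of cell in [0, 1],
        per land-cover class (dimensionless).
    biomass
        ``(year, pft, component, lat, lon)`` aboveground biomass, gC m⁻².
    soil_moisture
        ``(year, lat, lon)`` relative soil moisture (model units).
    pft_cover
        ``(pft, lat, lon)`` fractional cover per PFT; per-cell sum ≤ 1.
    """

    burned_fraction: xr.DataArray
    biomass: xr.DataArray
    soil_moisture: xr.DataArray
    pft_cover: xr.DataArray

    @property
    def years(self) -> np.ndarray:
        return self.burned_fraction.coords["year"].values

    @property
    def pfts(self) -> list[str]:
        return [str(p) for p in self.biomass.coords["pft"].values]

    def validate(self, grid: GridDomain | None = None) -> None:
        """Check physical invariants and axis consistency; raise on violation."""
        bf, bm, sm, cov = self.burned_fraction, self.biomass, self.soil_moisture, self.pft_cover
        for name, da, dims in (
            ("burned_fraction", bf, ("year", "landcover", "lat", "lon")),
            ("biomass", bm, ("year", "pft", "component", "lat", "lon")),
            ("soil_moisture", sm, ("year", "lat", "lon")),
            ("pft_cover", cov, ("pft", "lat", "lon")),
        ):
            if tuple(da.dims) != dims:
                raise GridError(f"{name} dims {da.dims} != {dims}")
            if not np.isfinite(da.values).all():
                raise ValidationError(f"{name} contains non-finite values")
        for name, da in (("burned_fraction", bf), ("biomass", bm), ("pft_cover", cov)):
            if (da.values < 0).any():
                raise ValidationError(f"{name} has negative values")
        if (bf.values > 1).any():
            raise ValidationError("burned fraction exceeds 1")
        if (cov.sum("pft").values > 1 + 1e-9).any():
            raise ValidationError("pft_cover sums above 1 in some cells")
        if list(bm.coords["pft"].values) != list(cov.coords["pft"].values):
            raise GridError("biomass and pft_cover disagree on the PFT axis")
        for da in (bm, sm):
            if not np.array_equal(da.coords["year"].values, self.years):
                raise GridError("fields disagree on the year axis")
        yrs = self.years
        if not np.array_equal(yrs, np.arange(yrs[0], yrs[-1] + 1)):
            raise GridError("year axis must be contiguous integer calendar years")
        if grid is not None:
            for name, da in (
                ("burned_fraction", bf),
                ("biomass", bm),
                ("soil_moisture", sm),
                ("pft_cover", cov),
            ):
                if da.sizes["lat"] != grid.shape[0] or da.sizes["lon"] != grid.shape[1]:
                    raise GridError(f"{name} spatial shape does not match the grid")
            lat = np.asarray(grid.lat_centers, dtype=float)
            if not np.all(np.diff(lat) > 0):
                raise GridError("grid latitude must be ascending")
            # active cells must carry a region label
            active = (bf.sum(("year", "landcover")).values > 0) | (
                bm.sum(("year", "pft", "component")).values > 0
            )
            if (active & (grid.region_id == 0)).any():
                raise ValidationError("cells with nonzero inputs lie outside every region")
        # degenerate cover: burning with no vegetated cover contributes nothing
        cover_total = cov.sum("pft").values
        burning = bf.sum(("year", "landcover")).values > 0
        n_bad = int(np.sum(burning & (cover_total <= 0)))
        if n_bad:
            logger.warning(
                "%d cells have burned fraction > 0 but zero PFT cover; "
                "their burned area will be dropped",
                n_bad,
            )


def burned_fraction_to_area(bundle: InputBundle, grid: GridDomain) -> xr.DataArray:
    """Convert burned fraction to absolute burned area (m² per cell).

    Totals are conserved under any regional partition because the
    conversion is per cell: ``area = fraction × cell_area``.
    """
    bf = bundle.burned_fraction
    if (bf.values > 1).any() or (bf.values < 0).any():
        raise ValidationError("burned fraction outside [0, 1]")
    area = xr.DataArray(
        grid.cell_area,
        coords={"lat": bf.coords["lat"], "lon": bf.coords["lon"]},
        dims=("lat", "lon"),
    )
    out = bf * area
    out.attrs["units"] = "m2"
    return out


# -- NetCDF round trip -------------------------------------------------------


def bundle_to_dataset(bundle: InputBundle, grid: GridDomain) -> xr.Dataset:
    """Pack an :class:`InputBundle` and grid into one CF-style Dataset."""
    ds = xr.Dataset(
        {
            "burned_fraction": bundle.burned_fraction,
            "biomass": bundle.biomass,
            "soil_moisture": bundle.soil_moisture,
            "pft_cover": bundle.pft_cover,
            "cell_area": (("lat", "lon"), grid.cell_area, {"units": "m2"}),
            "region_id": (("lat", "lon"), grid.region_id.astype(np.int32)),
        }
    )
    ds.attrs["Conventions"] = "CF-1.8-style"
    return ds


def save_bundle(bundle: InputBundle, grid: GridDomain, path) -> None:
    """Write bundle + grid to a NetCDF file (classic format)."""
    ds = bundle_to_dataset(bundle, grid)
    # NetCDF3 has no string type; encode label axes as indices + attribute
    enc = ds.copy()
    for dim in ("landcover", "pft", "component"):
        labels = [str(v) for v in ds.coords[dim].values]
        enc = enc.assign_coords({dim: np.arange(len(labels), dtype=np.int32)})
        enc.attrs[f"{dim}_labels"] = ",".join(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enc.to_netcdf(path, engine="scipy")


def load_bundle(path) -> tuple[InputBundle, GridDomain]:
    """Read a bundle + grid previously written by :func:`save_bundle`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for dim in ("landcover", "pft", "component"):
        labels = ds.attrs[f"{dim}_labels"].split(",")
        ds = ds.assign_coords({dim: labels})
    grid = GridDomain(
        lat_centers=ds.coords["lat"].values,
        lon_centers=ds.coords["lon"].values,
        cell_area=ds["cell_area"].values,
        region_id=ds["region_id"].values.astype(np.int64),
    )
    bundle = InputBundle(
        burned_fraction=ds["burned_fraction"],
        biomass=ds["biomass"],
        soil_moisture=ds["soil_moisture"],
        pft_cover=ds["pft_cover"],
    )
    return bundle, grid


def aggregate_monthly_to_annual(monthly: xr.DataArray) -> xr.DataArray:
    """Sum a ``(year, month, ...)`` field over months.

    Monthly inputs are collapsed to annual totals before any computation;
    the pipeline has no monthly-resolution outputs.
    """
    if "month" not in monthly.dims:
        raise GridError("expected a 'month' dimension")
    return monthly.sum("month")
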