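import numpy as np
import pytest
import xarray as xr

from pycfire import (
    COMPONENTS,
    LANDCOVERS,
    CombustionParams,
    InputBundle,
    PyCFactorTable,
    ScenarioConfig,
    build_grid,
    default_pft_taxonomy,
    generate_scenario,
    make_region_layout,
)


@pytest.fixture(scope="session")
def taxonomy():
    return default_pft_taxonomy()


@pytest.fixture(scope="session")
def params():
    return CombustionParams.default()


@pytest.fixture(scope="session")
def pyc_factors():
    return PyCFactorTable.default()


@pytest.fixture(scope="session")
def small_scenario():
    """A 10x8-cell, 30-year scenario shared by read-only tests."""
    cfg = ScenarioConfig(
        lat_bounds=(40.0, 45.0), lon_bounds=(100.0, 104.0), years=(1991, 2020), seed=7
    )
    return generate_scenario(cfg)


def tiny_grid(nlat=2, nlon=4, lat0=40.0, lon0=100.0):
    return build_grid(
        (lat0, lat0 + 0.5 * nlat), (lon0, lon0 + 0.5 * nlon), make_region_layout(nlat, nlon)
    )


def make_bundle(grid, taxonomy, rng, years=(2000, 2001), pfts=None):
    """Random dense bundle on an arbitrary grid for oracle comparisons."""
    nlat, nlon = grid.shape
    yrs = np.arange(years[0], years[1] + 1)
    ny = len(yrs)
    pfts = pfts or list(taxonomy.pft_ids)
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}

    bf = rng.uniform(0.0, 0.02, (ny, len(LANDCOVERS), nlat, nlon))
    biomass = rng.uniform(0.0, 3000.0, (ny, len(pfts), len(COMPONENTS), nlat, nlon))
    for j, p in enumerate(pfts):
        if taxonomy.landcover[p] == "nonforest":
            biomass[:, j, 1:3] = 0.0  # grass carries no woody mass
    sm = rng.uniform(0.1, 0.5, (ny, nlat, nlon))
    cover = rng.uniform(0.0, 1.0, (len(pfts), nlat, nlon))
    cover /= np.maximum(cover.sum(axis=0, keepdims=True), 1.0) * 1.05

    return InputBundle(
        burned_fraction=xr.DataArray(
            bf,
            coords={"year": yrs, "landcover": list(LANDCOVERS), **coords},
            dims=("year", "landcover", "lat", "lon"),
        ),
        biomass=xr.DataArray(
            biomass,
            coords={"year": yrs, "pft": pfts, "component": list(COMPONENTS), **coords},
            dims=("year", "pft", "component", "lat", "lon"),
        ),
        soil_moisture=xr.DataArray(
            sm, coords={"year": yrs, **coords}, dims=("year", "lat", "lon")
        ),
        pft_cover=xr.DataArray(
            cover, coords={"pft": pfts, **coords}, dims=("pft", "lat", "lon")
        ),
    )
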