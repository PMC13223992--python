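"""Synthetic scenario generator with the statistical structure of the
century-scale China fire record.

The generator emulates the inputs the accounting pipeline expects, so
every stage is testable without external downloads: burned fractions
that are sparse, concentrated in one "Northeast" hotspot region, and
follow a rising-then-declining national trend with a break near 2004;
multi-PFT biomass with leaf / aboveground sapwood / aboveground
heartwood / fruit components (forest ≫ grass); AR(1) interannual soil
moisture so the 5th/95th-percentile CC scaling is meaningful; and PFT
cover fields with forest dominant in the hotspot. Regions are
axis-aligned rectangles, not real provinces — the geometry is irrelevant
to the computation.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .grid_core import (
    COMPONENTS,
    LANDCOVERS,
    GridDomain,
    InputBundle,
    PFTTaxonomy,
    ValidationError,
    build_grid,
    default_pft_taxonomy,
)

#: Default per-component biomass means, gC m⁻² (forest canopy-scale vs
#: grassland herbaceous mass).
DEFAULT_FOREST_BIOMASS = {
    "leaf": 250.0,
    "aboveground_sapwood": 2500.0,
    "aboveground_heartwood": 3000.0,
    "fruit": 20.0,
}
DEFAULT_GRASS_BIOMASS = {
    "leaf": 150.0,
    "aboveground_sapwood": 0.0,
    "aboveground_heartwood": 0.0,
    "fruit": 5.0,
}


@dataclass(frozen=True)
class BATrend:
    """Piecewise-linear mean burned fraction with a prescribed break year."""

    start_level: float  # mean burned fraction in the first year
    pre_slope: float  # per-year change up to the break
    post_slope: float  # per-year change after the break
    break_year: int = 2004
    noise_cv: float = 0.10  # lognormal interannual CV (shared nationally)

    def level(self, years: np.ndarray) -> np.ndarray:
        y0 = years[0]
        pre = self.start_level + self.pre_slope * (years - y0)
        peak = self.start_level + self.pre_slope * (self.break_year - y0)
        post = peak + self.post_slope * (years - self.break_year)
        return np.clip(np.where(years <= self.break_year, pre, post), 0.0, None)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario."""

    lat_bounds: tuple[float, float] = (35.0, 45.0)
    lon_bounds: tuple[float, float] = (100.0, 110.0)
    years: tuple[int, int] = (1901, 2020)
    ba_trend: dict[str, BATrend] = field(
        default_factory=lambda: {
            "forest": BATrend(2.0e-3, 4.0e-5, -2.5e-4),
            "nonforest": BATrend(1.0e-3, 1.5e-5, -8.0e-5),
        }
    )
    hotspot_share: float = 0.79  # target fraction of burned area in region 1
    cell_noise_cv: float = 0.30  # per-cell lognormal CV
    burn_occurrence: float = 0.70  # per cell-year probability of any burning
    forest_biomass: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOREST_BIOMASS)
    )
    grass_biomass: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GRASS_BIOMASS)
    )
    biomass_spatial_cv: float = 0.20  # static spatial lognormal CV
    sm_mean: float = 0.30
    sm_sd: float = 0.05
    sm_rho: float = 0.60  # AR(1) autocorrelation
    hotspot_forest_cover: float = 0.75
    background_forest_cover: float = 0.35
    grass_cover: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hotspot_share < 1.0):
            raise ValidationError("hotspot_share must be in (0, 1)")
        if self.cell_noise_cv < 0 or any(t.noise_cv < 0 for t in self.ba_trend.values()):
            raise ValidationError("noise CV must be non-negative")
        y0, y1 = self.years
        for t in self.ba_trend.values():
            if not (y0 <= t.break_year <= y1):
                raise ValidationError("break_year outside the year range")


def make_region_layout(nlat: int, nlon: int) -> np.ndarray:
    """Partition the raster into 7 rectangles; region 1 is the
    northeast-corner hotspot."""
    if nlat < 2 or nlon < 4:
        raise ValidationError("grid too small to host 7 rectangular regions")
    mask = np.zeros((nlat, nlon), dtype=np.int64)
    half = nlat // 2
    edges = np.linspace(0, nlon, 5).astype(int)
    # top row of blocks (north; latitude ascending so high indices are north)
    top = [4, 6, 2, 1]  # North, Northwest, East, Northeast(hotspot)
    bot = [3, 5, 7, 7]  # Central, South, Southwest (last two merged)
    for k in range(4):
        mask[half:, edges[k]:edges[k + 1]] = top[k]
        mask[:half, edges[k]:edges[k + 1]] = bot[k]
    return mask


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape)


def _hotspot_weights(grid: GridDomain, share: float) -> np.ndarray:
    """Per-cell weights whose area-weighted hotspot share equals ``share``,
    normalized to area-weighted mean 1."""
    hot = grid.region_id == 1
    if not hot.any():
        raise ValidationError("layout has no hotspot (region 1) cells")
    a_hot = grid.cell_area[hot].sum()
    a_oth = grid.cell_area[~hot].sum()
    w = np.ones(grid.shape)
    w[hot] = share / (1.0 - share) * a_oth / a_hot
    w *= grid.cell_area.sum() / (w * grid.cell_area).sum()
    return w


def generate_scenario(cfg: ScenarioConfig) -> tuple[InputBundle, GridDomain, PFTTaxonomy]:
    """Generate a complete input bundle for one scenario."""
    taxonomy = default_pft_taxonomy()
    nlat = int(round((cfg.lat_bounds[1] - cfg.lat_bounds[0]) / 0.5))
    nlon = int(round((cfg.lon_bounds[1] - cfg.lon_bounds[0]) / 0.5))
    grid = build_grid(cfg.lat_bounds, cfg.lon_bounds, make_region_layout(nlat, nlon))
    years = np.arange(cfg.years[0], cfg.years[1] + 1)
    ny = len(years)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    weights = _hotspot_weights(grid, cfg.hotspot_share)

    # burned fraction: level(y) × national noise × cell weight × cell noise × occurrence
    bf = np.zeros((ny, len(LANDCOVERS), nlat, nlon))
    for il, lc in enumerate(LANDCOVERS):
        trend = cfg.ba_trend[lc]
        level = trend.level(years)
        eta = _lognormal_factors(rng, trend.noise_cv, ny)
        eps = _lognormal_factors(rng, cfg.cell_noise_cv, (ny, nlat, nlon))
        occ = rng.random((ny, nlat, nlon)) < cfg.burn_occurrence
        bf[:, il] = (
            level[:, None, None] * eta[:, None, None] * weights[None, :, :] * eps * occ
        )
    bf = np.clip(bf, 0.0, 1.0)

    # PFT cover: forest-dominated hotspot, boreal PFTs in the north
    pfts = list(taxonomy.pft_ids)
    forest_pfts = list(taxonomy.forest_pfts)
    grass_pfts = list(taxonomy.nonforest_pfts)
    cover = np.zeros((len(pfts), nlat, nlon))
    hot = grid.region_id == 1
    forest_total = np.where(hot, cfg.hotspot_forest_cover, cfg.background_forest_cover)
    lat_frac = (np.arange(nlat) + 0.5) / nlat  # 0 = south, 1 = north
    for j, p in enumerate(forest_pfts):
        cls = taxonomy.bioclimatic_class[p]
        bias = {"tropical": 1.0 - lat_frac, "temperate": 0.6 * np.ones(nlat), "boreal": lat_frac}[cls]
        raw = rng.gamma(2.0, 1.0, (nlat, nlon)) * bias[:, None]
        cover[pfts.index(p)] = raw
    fsum = cover[[pfts.index(p) for p in forest_pfts]].sum(axis=0)
    for p in forest_pfts:
        cover[pfts.index(p)] *= np.where(fsum > 0, forest_total / fsum, 0.0)
    for p in grass_pfts:
        cover[pfts.index(p)] = cfg.grass_cover / len(grass_pfts)

    # biomass: static spatial pattern, constant in time
    biomass = np.zeros((ny, len(pfts), len(COMPONENTS), nlat, nlon))
    for j, p in enumerate(pfts):
        means = cfg.forest_biomass if taxonomy.landcover[p] == "forest" else cfg.grass_biomass
        pattern = _lognormal_factors(rng, cfg.biomass_spatial_cv, (nlat, nlon))
        for kc, comp in enumerate(COMPONENTS):
            biomass[:, j, kc] = means.get(comp, 0.0) * pattern[None, :, :]

    # soil moisture: per-cell AR(1)
    sm = np.empty((ny, nlat, nlon))
    innov_sd = cfg.sm_sd * np.sqrt(1.0 - cfg.sm_rho**2)
    sm[0] = cfg.sm_mean + rng.normal(0.0, cfg.sm_sd, (nlat, nlon))
    for iy in range(1, ny):
        sm[iy] = cfg.sm_mean + cfg.sm_rho * (sm[iy - 1] - cfg.sm_mean) + rng.normal(
            0.0, innov_sd, (nlat, nlon)
        )
    sm = np.clip(sm, 1e-3, None)

    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    bundle = InputBundle(
        burned_fraction=xr.DataArray(
            bf,
            coords={"year": years, "landcover": list(LANDCOVERS), **coords},
            dims=("year", "landcover", "lat", "lon"),
            attrs={"units": "1"},
        ),
        biomass=xr.DataArray(
            biomass,
            coords={"year": years, "pft": pfts, "component": list(COMPONENTS), **coords},
            dims=("year", "pft", "component", "lat", "lon"),
            attrs={"units": "gC m-2"},
        ),
        soil_moisture=xr.DataArray(
            sm,
            coords={"year": years, **coords},
            dims=("year", "lat", "lon"),
            attrs={"units": "1"},
        ),
        pft_cover=xr.DataArray(
            cover, coords={"pft": pfts, **coords}, dims=("pft", "lat", "lon"),
            attrs={"units": "1"},
        ),
    )
    bundle.validate(grid)
    return bundle, grid, taxonomy


def generate_impulse_bundle(
    fire_year: int,
    cell: tuple[int, int],
    grid: GridDomain | None = None,
    taxonomy: PFTTaxonomy | None = None,
    years: tuple[int, int] = (1901, 2020),
    landcover: str = "forest",
    fraction: float = 0.01,
    biomass_means: dict[str, float] | None = None,
) -> tuple[InputBundle, GridDomain, PFTTaxonomy]:
    """Bundle with exactly one burning cell-year — the unit impulse used
    by oracle and impulse-response tests.

    Biomass is spatially uniform; soil moisture ramps linearly so the
    percentile bounds are non-degenerate.
    """
    taxonomy = taxonomy or default_pft_taxonomy()
    if grid is None:
        grid = build_grid((40.0, 42.0), (100.0, 102.0), make_region_layout(4, 4))
    nlat, nlon = grid.shape
    if not (0 <= cell[0] < nlat and 0 <= cell[1] < nlon):
        raise ValidationError(f"cell {cell} outside the {grid.shape} grid")
    yrs = np.arange(years[0], years[1] + 1)
    ny = len(yrs)
    if not years[0] <= fire_year <= years[1]:
        raise ValidationError("fire year outside the year range")

    pfts = list(taxonomy.pft_ids)
    bf = np.zeros((ny, len(LANDCOVERS), nlat, nlon))
    bf[fire_year - years[0], list(LANDCOVERS).index(landcover), cell[0], cell[1]] = fraction

    means = biomass_means or (
        DEFAULT_FOREST_BIOMASS if landcover == "forest" else DEFAULT_GRASS_BIOMASS
    )
    biomass = np.zeros((ny, len(pfts), len(COMPONENTS), nlat, nlon))
    for j, p in enumerate(pfts):
        if taxonomy.landcover[p] != landcover:
            continue
        for kc, comp in enumerate(COMPONENTS):
            biomass[:, j, kc] = means.get(comp, 0.0)

    sm = np.linspace(0.2, 0.4, ny)[:, None, None] * np.ones((ny, nlat, nlon))
    cover = np.zeros((len(pfts), nlat, nlon))
    lc_pfts = taxonomy.pfts_of_landcover(landcover)
    for p in lc_pfts:
        cover[pfts.index(p)] = 0.9 / len(lc_pfts)

    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    bundle = InputBundle(
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
        pft_cover=xr.DataArray(cover, coords={"pft": pfts, **coords}, dims=("pft", "lat", "lon")),
    )
    bundle.validate(grid)
    return bundle, grid, taxonomy
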