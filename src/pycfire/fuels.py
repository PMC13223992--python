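"""Fuel construction: biomass components -> time-lag classes -> fuel categories,
and proportional partition of burned area among PFTs.

Only aboveground biomass is treated as combustible. Leaves and fruit go
entirely to the 1-h class; aboveground sapwood and heartwood are split
4.5% / 7.5% / 21% / 67% across the 1-h / 10-h / 100-h / 1000-h classes.
The four time-lag classes map onto the three fuel categories used by the
PyC production factors: NWF = 1-h, FWF = 10-h + 100-h, CWF = 1000-h.
Both steps conserve mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .grid_core import (
    FUEL_CATEGORIES,
    TIMELAG_CLASSES,
    FuelTaxonomy,
    PFTTaxonomy,
    ValidationError,
    logger,
)

#: Default split of aboveground sapwood/heartwood across time-lag classes.
DEFAULT_WOODY_FRACTIONS = {"1h": 0.045, "10h": 0.075, "100h": 0.21, "1000h": 0.67}

#: Components routed entirely to the 1-h class.
LEAF_FRUIT = ("leaf", "fruit")
WOODY = ("aboveground_sapwood", "aboveground_heartwood")


@dataclass(frozen=True)
class AllocationScheme:
    """Fixed-in-space-and-time allocation of components to time-lag classes."""

    woody_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WOODY_FRACTIONS)
    )

    def __post_init__(self) -> None:
        fr = np.array([self.woody_fractions[t] for t in TIMELAG_CLASSES])
        if (fr < 0).any():
            raise ValidationError("woody allocation fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValidationError(f"woody allocation fractions sum to {fr.sum()}, not 1")


def allocate_fuel_classes(
    biomass_by_component: xr.DataArray, scheme: AllocationScheme | None = None
) -> xr.DataArray:
    """Allocate component biomass (gC m⁻²) to time-lag classes.

    ``biomass_by_component`` must carry a ``component`` dimension; any
    other dimensions (year, pft, lat, lon) broadcast through. Components
    outside the aboveground set (e.g. belowground pools in an input file)
    are ignored with a warning.
    """
    scheme = scheme or AllocationScheme()
    da = biomass_by_component
    if (da.values < 0).any():
        raise ValidationError("negative biomass component mass")
    comps = [str(c) for c in da.coords["component"].values]
    known = set(LEAF_FRUIT) | set(WOODY)
    extra = [c for c in comps if c not in known]
    if extra:
        logger.warning("ignoring non-aboveground biomass components: %s", extra)

    leaf_fruit = [c for c in comps if c in LEAF_FRUIT]
    woody = [c for c in comps if c in WOODY]
    fine = da.sel(component=leaf_fruit).sum("component") if leaf_fruit else 0.0
    wood = da.sel(component=woody).sum("component") if woody else 0.0

    layers = []
    for t in TIMELAG_CLASSES:
        layer = wood * scheme.woody_fractions[t]
        if t == "1h":
            layer = layer + fine
        layers.append(layer)
    out = xr.concat(layers, dim="timelag").assign_coords(timelag=list(TIMELAG_CLASSES))
    out.attrs["units"] = "gC m-2"
    return out


def aggregate_fuel_categories(
    load_by_timelag: xr.DataArray, taxonomy: FuelTaxonomy | None = None
) -> xr.DataArray:
    """Group time-lag class loads into the NWF / FWF / CWF fuel categories."""
    taxonomy = taxonomy or FuelTaxonomy()
    if (load_by_timelag.values < 0).any():
        raise ValidationError("negative fuel load")
    layers = [
        load_by_timelag.sel(timelag=list(taxonomy.timelags_of_category(cat))).sum("timelag")
        for cat in taxonomy.fuel_categories
    ]
    out = xr.concat(layers, dim="fuel_category").assign_coords(
        fuel_category=list(taxonomy.fuel_categories)
    )
    out.attrs["units"] = "gC m-2"
    return out


def fuel_load_by_category(
    biomass: xr.DataArray,
    scheme: AllocationScheme | None = None,
    taxonomy: FuelTaxonomy | None = None,
    pft_taxonomy: PFTTaxonomy | None = None,
    grass_all_nwf: bool = False,
) -> xr.DataArray:
    """Full fuel-load pipeline: components -> time-lag classes -> categories.

    Returns a field with a ``fuel_category`` dimension replacing
    ``component``. With ``grass_all_nwf`` every non-forest PFT's total
    mass is forced into NWF instead of going through the woody split
    (for inputs whose grass PFTs carry woody-like components).
    """
    by_cat = aggregate_fuel_categories(allocate_fuel_classes(biomass, scheme), taxonomy)
    if grass_all_nwf:
        if pft_taxonomy is None:
            raise ValidationError("grass_all_nwf requires a PFT taxonomy")
        total = biomass.sum("component")
        grass = [p for p in [str(v) for v in biomass.coords["pft"].values]
                 if pft_taxonomy.landcover.get(p) == "nonforest"]
        for p in grass:
            for cat in FUEL_CATEGORIES:
                sel = dict(pft=p, fuel_category=cat)
                by_cat.loc[sel] = total.sel(pft=p) if cat == "NWF" else 0.0
    return by_cat


def partition_burned_area(
    ba_landcover: xr.DataArray,
    pft_cover: xr.DataArray,
    taxonomy: PFTTaxonomy,
) -> xr.DataArray:
    """Partition per-land-cover burned area (m²) among PFTs by cover share.

    The share of PFT *i* is its cover divided by the total cover of PFTs
    in the same land-cover class — forest and non-forest burned areas are
    supplied separately, so shares are computed within the class. Cells
    with burned area but zero class cover contribute nothing; the dropped
    area is counted and logged.
    """
    if (ba_landcover.values < 0).any():
        raise ValidationError("negative burned area")
    pfts = [str(p) for p in pft_cover.coords["pft"].values]
    layers = []
    dropped = 0.0
    for pft in pfts:
        lc = taxonomy.landcover[pft]
        class_pfts = [p for p in pfts if taxonomy.landcover[p] == lc]
        class_cover = pft_cover.sel(pft=class_pfts).sum("pft")
        with np.errstate(invalid="ignore", divide="ignore"):
            share = xr.where(class_cover > 0, pft_cover.sel(pft=pft) / class_cover, 0.0)
        ba_lc = ba_landcover.sel(landcover=lc)
        layers.append((ba_lc * share).drop_vars("landcover", errors="ignore"))
        # dropped area is per-class, count it once per class
        if pft == class_pfts[0]:
            dropped += float(ba_lc.where(class_cover.values <= 0, 0.0).sum())
    if dropped > 0:
        logger.warning("dropped %.3g m2 of burned area in cells with zero class cover", dropped)
    out = xr.concat(layers, dim="pft").assign_coords(pft=pfts)
    out.attrs["units"] = "m2"
    return out
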