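"""Combustion parameters and moisture-driven combustion completeness (CC).

CC — the fraction of available fuel actually consumed — is bounded per
fuel category (coarse fuels burn less completely than fine ones) and
scaled linearly with soil moisture between the 5th and 95th percentiles
of each cell's soil-moisture record.

Two scaling directions are supported. The default ``dry_max`` follows the
GFED convention: drier conditions give more complete combustion, so soil
moisture at or below the 5th percentile maps to ``cc_max``. ``wet_max``
is the literal alternative reading (5th percentile -> ``cc_min``); the
two are mirror images about the CC midpoint.

Emission factors (EF, g CO2 per kg dry matter) and dry-matter carbon
content (DMCC) are assigned by bioclimatic class (tropical / temperate /
boreal / savanna) and mapped to PFTs through the taxonomy. Defaults ship
in a CSV parameter pack; every value is overridable in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from .grid_core import (
    BIOCLIMATIC_CLASSES,
    FUEL_CATEGORIES,
    PFTTaxonomy,
    ValidationError,
)


class ConfigurationError(KeyError):
    """Raised when a lookup references an unregistered PFT or class."""


def _read_pack(name: str) -> pd.DataFrame:
    with resources.files("pycfire.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class CombustionParams:
    """CC bounds per fuel category; EF and DMCC per bioclimatic class."""

    cc_min: dict[str, float]
    cc_max: dict[str, float]
    ef_co2: dict[str, float]  # g CO2 kg-1 DM
    dmcc: dict[str, float]  # carbon fraction of dry matter, (0, 1)

    def __post_init__(self) -> None:
        for cat in self.cc_min:
            lo, hi = self.cc_min[cat], self.cc_max[cat]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"CC bounds for {cat}: need 0 <= {lo} <= {hi} <= 1")
        for cls, v in self.dmcc.items():
            if not (0.0 < v < 1.0):
                raise ValidationError(f"DMCC for {cls} must be in (0, 1), got {v}")
        for cls, v in self.ef_co2.items():
            if v <= 0:
                raise ValidationError(f"EF for {cls} must be positive, got {v}")

    @classmethod
    def default(cls) -> "CombustionParams":
        """Load the shipped CSV parameter pack."""
        fc = _read_pack("fuel_category_params.csv").set_index("fuel_category")
        bc = _read_pack("bioclimatic_params.csv").set_index("bioclimatic_class")
        return cls(
            cc_min=fc["cc_min"].to_dict(),
            cc_max=fc["cc_max"].to_dict(),
            ef_co2=bc["ef_co2"].to_dict(),
            dmcc=bc["dmcc"].to_dict(),
        )

    def with_overrides(self, **overrides) -> "CombustionParams":
        """Return a copy with e.g. ``cc_max={"CWF": 0.6}`` merged in."""
        data = {
            "cc_min": dict(self.cc_min),
            "cc_max": dict(self.cc_max),
            "ef_co2": dict(self.ef_co2),
            "dmcc": dict(self.dmcc),
        }
        for key, sub in overrides.items():
            if key not in data:
                raise ConfigurationError(f"unknown parameter table {key!r}")
            data[key].update(sub)
        return CombustionParams(**data)


@dataclass(frozen=True)
class PyCFactorTable:
    """Fuel-category-specific PyC:CO2-C production factors with 95% CI."""

    p_pyc: dict[str, float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, mean in self.p_pyc.items():
            if not (0.0 < mean < 1.0):
                raise ValidationError(f"P_PyC for {cat} must be in (0, 1), got {mean}")
            if cat in self.ci95:
                lo, hi = self.ci95[cat]
                if not (lo <= mean <= hi):
                    raise ValidationError(f"P_PyC CI for {cat} does not bracket the mean")

    @classmethod
    def default(cls) -> "PyCFactorTable":
        df = _read_pack("pyc_factors.csv").set_index("fuel_category")
        return cls(
            p_pyc=df["p_pyc"].to_dict(),
            ci95={c: (df.loc[c, "ci_low"], df.loc[c, "ci_high"]) for c in df.index},
        )

    def sd(self, cat: str) -> float:
        """Normal-equivalent standard deviation from the 95% CI half-width."""
        lo, hi = self.ci95[cat]
        return (hi - lo) / (2.0 * 1.959963984540054)


# -- soil-moisture percentile bounds ----------------------------------------


def soil_moisture_percentiles(
    sm: xr.DataArray,
    p_lo: float = 5.0,
    p_hi: float = 95.0,
    mode: str = "per_cell",
) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray]:
    """Percentile bounds of the soil-moisture record.

    Returns ``(sm_lo, sm_hi, degenerate)`` per cell; ``degenerate`` flags
    cells where the bounds coincide (constant series), for which CC
    scaling falls back to the midpoint. Percentiles use linear
    interpolation between order statistics. ``mode="pooled"`` computes a
    single pair of bounds over all cells and years.
    """
    if sm.sizes["year"] < 2:
        raise ValidationError("need at least 2 years of soil moisture")
    if mode == "per_cell":
        lo = sm.quantile(p_lo / 100.0, dim="year", method="linear")
        hi = sm.quantile(p_hi / 100.0, dim="year", method="linear")
    elif mode == "pooled":
        qlo = float(np.quantile(sm.values, p_lo / 100.0))
        qhi = float(np.quantile(sm.values, p_hi / 100.0))
        template = sm.isel(year=0, drop=True)
        lo = xr.full_like(template, qlo)
        hi = xr.full_like(template, qhi)
    else:
        raise ValidationError(f"unknown percentile mode {mode!r}")
    lo = lo.drop_vars("quantile", errors="ignore")
    hi = hi.drop_vars("quantile", errors="ignore")
    degenerate = hi <= lo
    return lo, hi, degenerate


def scale_cc(
    sm_t: xr.DataArray,
    bounds: tuple[xr.DataArray, xr.DataArray],
    params: CombustionParams,
    direction: str = "dry_max",
) -> xr.DataArray:
    """Linearly scale CC with soil moisture, clipped to [cc_min, cc_max].

    ``sm_t`` may be a single year ``(lat, lon)`` or the full ``(year, lat,
    lon)`` stack. Output gains a leading ``fuel_category`` dimension.
    Degenerate bounds (sm_lo == sm_hi) give the midpoint CC.
    """
    if direction not in ("dry_max", "wet_max"):
        raise ValidationError(f"unknown CC direction {direction!r}")
    sm_lo, sm_hi = bounds
    span = sm_hi - sm_lo
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = xr.where(span > 0, (sm_t - sm_lo) / span, 0.5)
    frac = frac.clip(0.0, 1.0)
    if direction == "dry_max":
        frac = 1.0 - frac  # drier -> more complete combustion
    layers = []
    for cat in FUEL_CATEGORIES:
        lo, hi = params.cc_min[cat], params.cc_max[cat]
        layers.append(lo + frac * (hi - lo))
    out = xr.concat(layers, dim="fuel_category").assign_coords(
        fuel_category=list(FUEL_CATEGORIES)
    )
    out = out.transpose("fuel_category", *sm_t.dims)
    out.attrs["units"] = "1"
    return out


def lookup_pft_params(
    pft: str, taxonomy: PFTTaxonomy, params: CombustionParams
) -> tuple[float, float]:
    """Return ``(ef_co2, dmcc)`` for a PFT via its bioclimatic class."""
    if pft not in taxonomy.bioclimatic_class:
        raise ConfigurationError(f"PFT {pft!r} not registered in the taxonomy")
    cls = taxonomy.bioclimatic_class[pft]
    try:
        return params.ef_co2[cls], params.dmcc[cls]
    except KeyError as exc:
        raise ConfigurationError(f"no parameters for bioclimatic class {cls!r}") from exc
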