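"""Monte Carlo uncertainty propagation and one-at-a-time sensitivity.

The inventory equation is linear in every perturbed parameter, so a
perturbation acts as an exact multiplicative rescaling of the affected
(PFT, fuel-category) terms of the national decomposition: fuel load,
EF, CC and P_PyC scale their terms by ``draw/mean``, while DMCC enters
through 1/DMCC and scales by ``mean/draw``. Parameters tied to the same
fuel category (P_PyC_j and CC_j) therefore produce identical responses.
Rescaling the base inventory is exact — no re-run of the grid is needed
— and CC perturbations are deliberately not re-clipped to the CC bounds,
which is what makes that equivalence hold.

Monte Carlo draws are independent across parameters (no covariance
information is available) and shared across all cells and years within
an iteration: parameter error is systematic, and per-cell independence
would artificially shrink national confidence intervals. Out-of-bounds
draws are redrawn (up to 100 attempts) rather than truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .combustion import CombustionParams, PyCFactorTable
from .grid_core import BIOCLIMATIC_CLASSES, FUEL_CATEGORIES, LANDCOVERS, PFTTaxonomy
from .pyc_core import GC_PER_TGC, PyCResult

#: Default coefficient of variation for the national fuel-load scale,
#: motivated by the multi-model spread of simulated biomass (~18%).
DEFAULT_FUEL_LOAD_CV = 0.18

#: One-at-a-time perturbation levels (relative).
DEFAULT_LEVELS = (-0.10, -0.05, 0.05, 0.10)


class UnknownParameterError(KeyError):
    """Raised when a distribution or target names no known parameter."""


@dataclass(frozen=True)
class ParamDistribution:
    """Normal sampling distribution for one scalar parameter.

    ``name`` follows the scheme ``fuel_load``, ``p_pyc_<CAT>``,
    ``cc_<CAT>``, ``ef_<class>``, ``dmcc_<class>``.
    """

    name: str
    mean: float
    sd: float
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be non-negative")
        if not (self.bounds[0] <= self.mean <= self.bounds[1]):
            raise ValueError(f"{self.name}: bounds {self.bounds} do not contain mean {self.mean}")

    def draw(self, rng: np.random.Generator, max_attempts: int = 100) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(max_attempts):
            v = rng.normal(self.mean, self.sd)
            if self.bounds[0] <= v <= self.bounds[1]:
                return float(v)
        raise ValueError(f"{self.name}: no in-bounds draw after {max_attempts} attempts")


def _parse_param(name: str) -> tuple[str, str | None]:
    """Split a parameter name into (kind, key); validate against the schemes."""
    if name in ("fuel_load", "fuel_load_scale"):
        return "fuel_load", None
    for prefix, kind, keys in (
        ("p_pyc_", "p_pyc", FUEL_CATEGORIES),
        ("cc_", "cc", FUEL_CATEGORIES),
        ("ef_", "ef", BIOCLIMATIC_CLASSES),
        ("dmcc_", "dmcc", BIOCLIMATIC_CLASSES),
    ):
        if name.startswith(prefix):
            key = name[len(prefix):]
            if key not in keys:
                raise UnknownParameterError(f"{name}: unknown key {key!r} (expect one of {keys})")
            return kind, key
    raise UnknownParameterError(f"unrecognized parameter name {name!r}")


def term_multiplier(
    name: str,
    factor: float,
    pfts: list[str],
    taxonomy: PFTTaxonomy,
) -> np.ndarray:
    """(pft, fuel_category) multiplier implied by scaling ``name`` by ``factor``.

    ``factor`` is the ratio draw/mean of the parameter itself; for DMCC
    the term response is its reciprocal (the 1/DMCC term).
    """
    kind, key = _parse_param(name)
    mult = np.ones((len(pfts), len(FUEL_CATEGORIES)))
    if kind == "fuel_load":
        mult *= factor
    elif kind in ("p_pyc", "cc"):
        mult[:, list(FUEL_CATEGORIES).index(key)] *= factor
    elif kind == "ef":
        sel = [i for i, p in enumerate(pfts) if taxonomy.bioclimatic_class[p] == key]
        mult[sel, :] *= factor
    else:  # dmcc
        sel = [i for i, p in enumerate(pfts) if taxonomy.bioclimatic_class[p] == key]
        mult[sel, :] /= factor
    return mult


def default_distributions(
    params: CombustionParams,
    pyc_factors: PyCFactorTable,
    fuel_load_cv: float = DEFAULT_FUEL_LOAD_CV,
    ef_cv: float = 0.10,
    dmcc_cv: float = 0.05,
) -> list[ParamDistribution]:
    """Distributions for every sampled parameter.

    P_PyC standard deviations come from the 95% CIs of the factor table;
    the remaining CVs are configurable placeholders to be overridden when
    better constraints are available.
    """
    dists = [
        ParamDistribution("fuel_load", 1.0, fuel_load_cv, bounds=(0.0, np.inf))
    ]
    for cat in FUEL_CATEGORIES:
        mean = pyc_factors.p_pyc[cat]
        dists.append(ParamDistribution(f"p_pyc_{cat}", mean, pyc_factors.sd(cat), (0.0, 1.0)))
    for cls in BIOCLIMATIC_CLASSES:
        ef = params.ef_co2[cls]
        dm = params.dmcc[cls]
        dists.append(ParamDistribution(f"ef_{cls}", ef, ef_cv * ef, (0.0, np.inf)))
        dists.append(ParamDistribution(f"dmcc_{cls}", dm, dmcc_cv * dm, (0.05, 0.95)))
    return dists


def monte_carlo(
    base: PyCResult,
    taxonomy: PFTTaxonomy,
    dists: list[ParamDistribution],
    n_iter: int = 1000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Propagate parameter uncertainty through the inventory.

    Returns, per land-cover class, a DataFrame indexed by year with the
    plug-in ``point`` estimate and the empirical 2.5/97.5 percentile
    envelope ``ci_low``/``ci_high`` over ``n_iter`` iterations (TgC yr⁻¹).
    Deterministic under ``seed``; iteration substreams are spawned from
    one seed sequence so results are stable under parallel evaluation.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    for d in dists:
        _parse_param(d.name)
    pfts = [str(p) for p in base.pyc_national.coords["pft"].values]
    # (year, lc, pft, cat) base terms in TgC
    terms = base.pyc_national.values / GC_PER_TGC
    n_year = terms.shape[0]

    streams = np.random.SeedSequence(seed).spawn(n_iter)
    samples = np.empty((n_iter, n_year, len(LANDCOVERS)))
    for it in range(n_iter):
        rng = np.random.default_rng(streams[it])
        mult = np.ones((len(pfts), len(FUEL_CATEGORIES)))
        for d in dists:
            v = d.draw(rng)
            mult *= term_multiplier(d.name, v / d.mean, pfts, taxonomy)
        samples[it] = np.einsum("ylpc,pc->yl", terms, mult)

    out = {}
    point = terms.sum(axis=(2, 3))
    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    years = base.years
    for il, lc in enumerate(LANDCOVERS):
        out[lc] = pd.DataFrame(
            {"point": point[:, il], "ci_low": lo[:, il], "ci_high": hi[:, il]}, index=years
        )
    return out


#: The 13 one-at-a-time targets: fuel load; P_PyC and CC per fuel
#: category; DMCC and EF per forest bioclimatic class.
DEFAULT_SENSITIVITY_TARGETS = (
    ["fuel_load"]
    + [f"p_pyc_{c}" for c in FUEL_CATEGORIES]
    + [f"cc_{c}" for c in FUEL_CATEGORIES]
    + [f"dmcc_{c}" for c in ("tropical", "temperate", "boreal")]
    + [f"ef_{c}" for c in ("tropical", "temperate", "boreal")]
)


def sensitivity(
    base: PyCResult,
    taxonomy: PFTTaxonomy,
    targets: list[str] | tuple[str, ...] = DEFAULT_SENSITIVITY_TARGETS,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    landcover: str = "forest",
) -> pd.DataFrame:
    """One-at-a-time perturbation of each target parameter.

    Returns a tidy frame with columns ``parameter``, ``level``, ``year``,
    ``delta_pyc`` (TgC yr⁻¹, perturbed − base, for the chosen land-cover
    class). Multiplicative parameters respond by exactly the perturbation
    fraction on their terms; DMCC responds by ``1/(1+δ) − 1``.
    """
    pfts = [str(p) for p in base.pyc_national.coords["pft"].values]
    il = list(LANDCOVERS).index(landcover)
    terms = base.pyc_national.values[:, il] / GC_PER_TGC  # (year, pft, cat)
    base_total = terms.sum(axis=(1, 2))
    years = base.years
    rows = []
    for name in targets:
        _parse_param(name)
        for level in levels:
            mult = term_multiplier(name, 1.0 + level, pfts, taxonomy)
            perturbed = np.einsum("ypc,pc->y", terms, mult)
            for iy, year in enumerate(years):
                rows.append(
                    {
                        "parameter": name,
                        "level": level,
                        "year": int(year),
                        "delta_pyc": perturbed[iy] - base_total[iy],
                    }
                )
    return pd.DataFrame(rows)


def sensitivity_summary(sens: pd.DataFrame) -> pd.DataFrame:
    """Mean annual ΔPyC per parameter × level (TgC yr⁻¹)."""
    return (
        sens.groupby(["parameter", "level"])["delta_pyc"].mean().unstack("level")
    )
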