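"""Two-pool exponential decay of PyC and cumulative stock accounting.

PyC is split into a labile pool (fraction *a*, fast rate k_l) and a
stable pool (fraction *b*, slow rate k_s); the percentage remaining after
*t* years is ``a·e^(−k_l·t) + b·e^(−k_s·t)``. Defaults (a = 9.1%,
b = 90.9%, k_l = 0.5 yr⁻¹, k_s = 1.1e-3 yr⁻¹) follow biochar/PyC field
and incubation syntheses. Annual discretization with integer lags:
production arrives at the start of its year, so same-year production is
undecayed (lag-0 factor 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_core import ValidationError


@dataclass(frozen=True)
class DecayParams:
    a: float = 9.1  # labile fraction, percent
    b: float = 90.9  # stable fraction, percent
    k_l: float = 0.5  # labile decomposition rate, yr^-1
    k_s: float = 1.1e-3  # stable decomposition rate, yr^-1

    def __post_init__(self) -> None:
        if abs(self.a + self.b - 100.0) > 1e-9:
            raise ValidationError(f"pool fractions must sum to 100%, got {self.a + self.b}")
        if not (self.k_l > self.k_s > 0):
            raise ValidationError("need k_l > k_s > 0")


def remaining_fraction(t, p: DecayParams | None = None) -> np.ndarray | float:
    """Percent of initial PyC remaining after ``t`` years (t ≥ 0).

    Strictly decreasing in t; 100% at t = 0; → 0 as t → ∞.
    """
    p = p or DecayParams()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("decay time must be non-negative")
    out = p.a * np.exp(-p.k_l * t_arr) + p.b * np.exp(-p.k_s * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cumulative_stock(
    production: pd.Series, p: DecayParams | None = None
) -> pd.DataFrame:
    """Cumulative PyC stock remaining each year after two-pool decay.

    ``production`` is an annual series (TgC yr⁻¹) indexed by contiguous
    integer years. ``stock(Y) = Σ_{y ≤ Y} production(y) ×
    remaining_fraction(Y − y) / 100``; the convolution is linear, so
    stocks of summed series add.
    """
    p = p or DecayParams()
    years = np.asarray(production.index, dtype=int)
    vals = np.asarray(production.values, dtype=float)
    if len(years) == 0:
        raise ValidationError("empty production series")
    if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise ValidationError("production series must have contiguous integer years")
    if np.any(vals < 0):
        raise ValidationError("negative production")
    kernel = remaining_fraction(np.arange(len(years)), p) / 100.0
    stock = np.convolve(vals, kernel)[: len(years)]
    return pd.DataFrame({"year": years, "production": vals, "stock": stock}).set_index("year")
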