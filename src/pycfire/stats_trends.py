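"""Period-wise OLS trends and descriptive statistics for annual series.

Trends are ordinary least squares fits of an annual series on calendar
year over fixed, configured periods (breakpoints are prescribed, not
detected), with the two-sided t-test p-value and a p < 0.05 significance
rule. The break year belongs to both sub-periods, mirroring the
"1901 to 2004" / "2004 to 2020" period notation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid_core import ValidationError

ALPHA = 0.05


class InsufficientDataError(ValueError):
    """Raised when a period holds fewer than 3 annual values."""


@dataclass(frozen=True)
class TrendResult:
    period: tuple[int, int]  # inclusive start/end year
    slope: float  # TgC yr^-2
    intercept: float  # TgC yr^-1 at the period-mean year
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


def linear_trend(series: pd.Series, period: tuple[int, int] | None = None) -> TrendResult:
    """OLS slope of an annual series over ``period`` (inclusive).

    Years are centered before the fit for conditioning; the slope is
    unchanged and the reported intercept refers to the centered axis.
    A zero-variance series yields slope 0 with p = 1.
    """
    years = np.asarray(series.index, dtype=float)
    if period is None:
        period = (int(years.min()), int(years.max()))
    sel = (years >= period[0]) & (years <= period[1])
    t = years[sel]
    y = np.asarray(series.values, dtype=float)[sel]
    if len(t) < 3:
        raise InsufficientDataError(f"period {period} holds {len(t)} points; need >= 3")
    if np.ptp(y) == 0.0:
        return TrendResult(period=period, slope=0.0, intercept=float(y[0]), p_value=1.0,
                           significant=False)
    fit = stats.linregress(t - t.mean(), y)
    p = float(fit.pvalue)
    return TrendResult(
        period=period,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=p,
        significant=p < ALPHA,
    )


def piecewise_trends(
    series: pd.Series, break_year: int = 2004
) -> tuple[TrendResult, TrendResult]:
    """Independent OLS fits before and after a prescribed break year.

    The break year is included in both periods.
    """
    years = np.asarray(series.index, dtype=int)
    if not (years.min() < break_year < years.max()):
        raise ValidationError(
            f"break year {break_year} must lie strictly inside {years.min()}–{years.max()}"
        )
    pre = linear_trend(series, (int(years.min()), break_year))
    post = linear_trend(series, (break_year, int(years.max())))
    return pre, post


def descriptives(series: pd.Series) -> dict[str, float]:
    """Median, quartiles (linear interpolation), mean, and sample sd.

    The sd of a single value is undefined and reported as NaN.
    """
    y = np.asarray(series.values, dtype=float)
    if len(y) == 0:
        raise ValidationError("empty series")
    return {
        "median": float(np.quantile(y, 0.5)),
        "q25": float(np.quantile(y, 0.25)),
        "q75": float(np.quantile(y, 0.75)),
        "mean": float(np.mean(y)),
        "sd": float(np.std(y, ddof=1)) if len(y) > 1 else float("nan"),
    }


def trend_table(series_by_name: dict[str, pd.Series],
                periods: dict[str, list[tuple[int, int]]]) -> pd.DataFrame:
    """Tidy per-series, per-period slope/p/significance table."""
    rows = []
    for name, series in series_by_name.items():
        for period in periods.get(name, periods.get("default", [])):
            tr = linear_trend(series, period)
            rows.append(
                {
                    "series": name,
                    "start": period[0],
                    "end": period[1],
                    "slope": tr.slope,
                    "p_value": tr.p_value,
                    "significant": tr.significant,
                }
            )
    return pd.DataFrame(rows)
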