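"""Width-trend regression and dynamic-change rates.

The trend of average mangrove width over study years is an ordinary
least-squares line with calendar year as the regressor, so the slope has
units of metres per year; significance is the classical two-sided t test
of the slope at alpha = 0.05 (series failing it are deemed trendless).
Percent rates follow the convention of reporting the total change relative
to the initial value, divided by the span in years; the two-epoch
single-factor dynamic-change rate K = (Ub - Ua) / Ua / T * 100 uses the
same convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WidthSeries",
    "TrendResult",
    "fit_width_trend",
    "annual_percent_rate",
    "dynamic_change",
    "trend_table",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Too few points (or no year variance) for a trend fit."""


@dataclass(frozen=True)
class WidthSeries:
    """Ordered (year, width) observations for one unit of analysis."""

    unit_id: str
    years: tuple[float, ...]
    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=float)
        if len(self.years) != len(self.widths):
            raise ValueError("years and widths must have equal length")
        if len(y) >= 2 and not (np.diff(y) > 0).all():
            raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class TrendResult:
    """OLS slope with its test, plus the change/rate arithmetic.

    ``total_change`` is the observed endpoint difference (last minus first
    width); ``fitted_change`` is slope times span — the two differ under
    noise and both are exposed.  ``percent_rate`` is the endpoint change
    relative to the initial width per year of span, in percent.
    """

    unit_id: str
    slope: float  # m / year
    intercept: float
    p_value: float
    significant: bool
    slope_ci: tuple[float, float]  # 95% CI of the slope
    total_change: float  # m, endpoint difference
    fitted_change: float  # m, slope x span
    percent_rate: float  # % / year on the initial width
    span_years: float


def fit_width_trend(series: WidthSeries, alpha: float = 0.05) -> TrendResult:
    """Fit the width-vs-year line and test the slope against zero."""
    years = np.asarray(series.years, dtype=float)
    widths = np.asarray(series.widths, dtype=float)
    if years.size < 3:
        raise InsufficientDataError(f"{series.unit_id}: need >= 3 points, got {years.size}")
    if np.ptp(years) == 0:
        raise InsufficientDataError(f"{series.unit_id}: zero variance in years")
    fit = stats.linregress(years, widths)
    dof = years.size - 2
    tcrit = stats.t.ppf(0.975, dof)
    span = float(years[-1] - years[0])
    total = float(widths[-1] - widths[0])
    p = float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0
    rate = annual_percent_rate(float(widths[0]), total, span) if widths[0] > 0 else float("nan")
    return TrendResult(
        unit_id=series.unit_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=p,
        significant=bool(p < alpha),
        slope_ci=(float(fit.slope - tcrit * fit.stderr), float(fit.slope + tcrit * fit.stderr)),
        total_change=total,
        fitted_change=float(fit.slope) * span,
        percent_rate=rate,
        span_years=span,
    )


def annual_percent_rate(initial: float, total_change: float, span_years: float) -> float:
    """Percent-per-year rate of a total change on an initial value.

    rate = (total_change / initial) / span * 100
    """
    if initial <= 0:
        raise ValueError("initial value must be positive")
    if span_years <= 0:
        raise ValueError("span must be positive")
    return total_change / initial / span_years * 100.0


def dynamic_change(ua: float, ub: float, span_years: float) -> float:
    """Single-factor dynamic-change rate K = (Ub - Ua) / Ua / T * 100 (%/yr)."""
    if ua <= 0:
        raise ValueError("initial attribute value must be positive")
    if span_years <= 0:
        raise ValueError("span must be positive")
    return (ub - ua) / ua / span_years * 100.0


def trend_table(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit every unit in a long-format (unit_id, year, amw_m) table.

    Units with fewer than 3 observations are dropped.
    """
    rows = []
    for unit, g in df.groupby("unit_id", sort=True):
        g = g.sort_values("year")
        if len(g) < 3:
            continue
        res = fit_width_trend(
            WidthSeries(str(unit), tuple(g["year"]), tuple(g["amw_m"])), alpha=alpha
        )
        rows.append(
            {
                "unit_id": res.unit_id,
                "slope_m_per_yr": res.slope,
                "intercept": res.intercept,
                "p_value": res.p_value,
                "significant": res.significant,
                "total_change_m": res.total_change,
                "fitted_change_m": res.fitted_change,
                "percent_rate_per_yr": res.percent_rate,
                "span_years": res.span_years,
            }
        )
    return pd.DataFrame(rows)
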