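"""Bloom-area time series: smoothing, monthly aggregation, additive seasonal
decomposition, and matching areas to water-quality sampling dates.

The decomposition is the classical additive one: trend-cycle from a centered
2x12 moving average, seasonal factors as per-calendar-month means of the
detrended series re-centered to sum to zero, irregular as the remainder.
Value = trend + seasonal + irregular wherever the trend is defined.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections.abc import Iterable

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import seasonal_decompose

from .errors import ValidationError

MONTH_NAMES = ("January", "February", "March", "April", "May", "June",
               "July", "August", "September", "October", "November",
               "December")


@dataclasses.dataclass
class AreaSeries:
    """Dated bloom areas (km²) at daily or monthly cadence.

    Dates are strictly ascending.  Areas are non-negative by default;
    model-generated series (which may undershoot zero) can opt out with
    ``allow_negative=True``.
    """

    entries: pd.Series
    cadence: str = "daily"
    allow_negative: bool = False

    def __post_init__(self):
        if self.cadence not in ("daily", "monthly"):
            raise ValidationError(f"unknown cadence {self.cadence!r}")
        s = pd.Series(self.entries, dtype=float)
        s.index = pd.DatetimeIndex(s.index)
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValidationError("dates must be strictly ascending")
        if not self.allow_negative and (s.dropna() < 0).any():
            raise ValidationError("areas must be non-negative")
        self.entries = s

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[_dt.date, float]],
                   cadence: str = "daily", **kw) -> "AreaSeries":
        dates, areas = zip(*pairs)
        return cls(pd.Series(list(areas), index=pd.DatetimeIndex(dates)),
                   cadence=cadence, **kw)

    @classmethod
    def from_csv(cls, path, cadence: str = "daily", **kw) -> "AreaSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(pd.Series(df["area_km2"].to_numpy(),
                             index=pd.DatetimeIndex(df["date"])),
                   cadence=cadence, **kw)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "date": self.entries.index.strftime("%Y-%m-%d"),
            "area_km2": self.entries.to_numpy(),
        }).to_csv(path, index=False)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.entries.index

    @property
    def areas(self) -> np.ndarray:
        return self.entries.to_numpy()

    def __len__(self) -> int:
        return len(self.entries)


@dataclasses.dataclass
class DecompositionResult:
    """Additive decomposition into trend, seasonal, and irregular parts.

    ``seasonal_factors`` is indexed by calendar month (1..12) and sums to
    zero; ``trend`` is NaN at the 6 edge points on each side where the
    centered 2x12 average is undefined.
    """

    observed: pd.Series
    trend: pd.Series
    seasonal: pd.Series
    seasonal_factors: pd.Series
    adjusted: pd.Series
    irregular: pd.Series


def moving_average(series: AreaSeries, window: int) -> AreaSeries:
    """Centered moving average with an odd window.

    Near the edges the window shrinks symmetrically to the points available,
    so the output has the same length and dates as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    x = series.areas
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h:i + h + 1].mean()
    return AreaSeries(pd.Series(out, index=series.dates),
                      cadence=series.cadence,
                      allow_negative=series.allow_negative)


def monthly_mean(series: AreaSeries) -> AreaSeries:
    """Mean area per calendar month (zeros included, missing days excluded).

    Months with no observations at all produce no entry.  Output entries are
    dated at the first of each month.
    """
    if series.cadence != "daily":
        raise ValidationError("monthly_mean expects a daily series")
    grouped = series.entries.groupby(series.entries.index.to_period("M")).mean()
    grouped.index = grouped.index.to_timestamp()
    return AreaSeries(grouped, cadence="monthly",
                      allow_negative=series.allow_negative)


def fill_monthly_gaps(series: AreaSeries) -> tuple[AreaSeries, np.ndarray]:
    """Fill missing calendar months by linear interpolation.

    Returns the gap-free monthly series and a boolean array flagging the
    interpolated entries.  Leading/trailing months are never invented.
    """
    if series.cadence != "monthly":
        raise ValidationError("fill_monthly_gaps expects a monthly series")
    full_index = pd.date_range(series.dates[0], series.dates[-1], freq="MS")
    reindexed = series.entries.reindex(full_index)
    filled_mask = reindexed.isna().to_numpy()
    filled = reindexed.interpolate(method="linear")
    return (AreaSeries(filled, cadence="monthly",
                       allow_negative=series.allow_negative), filled_mask)


def _check_contiguous_monthly(series: AreaSeries) -> None:
    expected = pd.date_range(series.dates[0], periods=len(series), freq="MS")
    actual = pd.DatetimeIndex(series.dates.to_period("M").to_timestamp())
    if not actual.equals(expected):
        raise ValidationError(
            "monthly series has gaps; fill them first (fill_monthly_gaps)"
        )


def decompose_additive(series: AreaSeries, period: int = 12) -> DecompositionResult:
    """Classical additive seasonal decomposition of a gap-free monthly series."""
    if len(series) < 2 * period:
        raise ValidationError(
            f"need at least {2 * period} observations, got {len(series)}"
        )
    _check_contiguous_monthly(series)
    s = series.entries.copy()
    s.index = pd.DatetimeIndex(s.index.to_period("M").to_timestamp())
    res = seasonal_decompose(s, model="additive", period=period,
                             extrapolate_trend=0)
    seasonal = res.seasonal
    # one factor per calendar month, re-centered (statsmodels already centers)
    factors = seasonal.groupby(seasonal.index.month).first()
    factors = factors - factors.mean()
    factors.index.name = "month"
    seasonal = pd.Series(factors.loc[s.index.month].to_numpy(), index=s.index)
    return DecompositionResult(
        observed=s,
        trend=res.trend,
        seasonal=seasonal,
        seasonal_factors=factors,
        adjusted=s - seasonal,
        irregular=s - res.trend - seasonal,
    )


def seasonal_extremes(d: DecompositionResult) -> tuple[str, float, str, float]:
    """(month of max factor, max, month of min factor, min); ties → earlier month."""
    f = d.seasonal_factors
    imax = int(np.argmax(f.to_numpy()))
    imin = int(np.argmin(f.to_numpy()))
    return (MONTH_NAMES[imax], float(f.iloc[imax]),
            MONTH_NAMES[imin], float(f.iloc[imin]))


def match_area_to_sampling(
    daily: AreaSeries, sampling_date: _dt.date, window_days: int = 7
) -> float | None:
    """Mean of strictly positive areas within ±window_days of a sampling date.

    Zero-area days are excluded (a cloud-free day with no detected bloom says
    nothing about bloom intensity at the sampling site); returns ``None``
    when no positive observation falls inside the window.
    """
    if window_days < 0:
        raise ValidationError("window_days must be non-negative")
    center = pd.Timestamp(sampling_date)
    delta = (daily.dates - center).days
    in_window = np.abs(delta) <= window_days
    vals = daily.areas[in_window]
    vals = vals[vals > 0]
    if len(vals) == 0:
        return None
    return float(vals.mean())
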