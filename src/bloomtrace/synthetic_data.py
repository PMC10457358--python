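"""Synthetic inputs for the whole pipeline.

Three generators, all bit-reproducible per seed:

* paired low/high-sensitivity scenes with planted bloom patches, coastal
  sediment patches and clouds.  The high-sensitivity (atmospherically
  corrected) level equals the low level plus a constant NIR offset δ, so
  every low-level extraction is a subset of the high-level one.  Sediment
  amplitudes sit between the two detection limits: invisible at the shared
  threshold in the low level, extracted as false positives in the high level
  — the phenomenology the dual-level weakening is designed to suppress;
* monthly bloom-area series with a stable-then-rising piecewise-linear
  trend, a fixed zero-sum monthly seasonal vector, and seasonal-MA noise,
  truncated at zero;
* meteorology / water-quality driver tables with configurable couplings
  (warm-water positive, wind and pressure negative, oxygen negative,
  petroleum positive).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
import pandas as pd

from .bloom_series import AreaSeries
from .errors import ValidationError
from .sarima_model import SarimaParams, expand_ma
from .sensor_scene import (
    HIGH_SENSITIVITY,
    LOW_SENSITIVITY,
    Scene,
    ScenePair,
    SensorSpec,
    get_sensor,
)

#: Monthly seasonal deviations (km²) used as the generator default: summer
#: bloom maximum in September, late-winter minimum in March, zero sum.
DEFAULT_SEASONAL_FACTORS = (
    -0.22, -0.29, -0.30, -0.26, 0.03, 0.12,
    0.30, 0.39, 0.40, 0.03, -0.09, -0.11,
)


@dataclasses.dataclass(frozen=True)
class SceneGenConfig:
    """Design of one synthetic scene pair.

    Patches are (row, col, radius_px) disks added to the NIR band.  With the
    defaults (10 m pixels, shared threshold 0.045, minimum area 0.7 km²) the
    bloom patch clears the threshold at both levels (~1.1 km²), the sediment
    patch (~0.8 km²) only at the high-sensitivity level, and clear water at
    neither.
    """

    grid_shape: tuple[int, int] = (256, 256)
    sensor: SensorSpec | str = "s2-like"
    background: tuple[float, float, float] = (0.03, 0.02, 0.01)  # red,nir,swir
    noise_sigma: float = 0.002
    bloom_patches: tuple[tuple[int, int, int], ...] = ((140, 160, 60),)
    bloom_amplitude: float = 0.08
    sediment_patches: tuple[tuple[int, int, int], ...] = ((60, 62, 50),)
    sediment_amplitude: float = 0.03
    sensitivity_offset: float = 0.03  # δ: high-level NIR minus low-level NIR
    cloud_fraction: float = 0.0
    coast_px: int = 8  # land strip width (columns) on the grid's left edge
    date: _dt.date = _dt.date(2021, 7, 10)
    seed: int = 0

    def __post_init__(self):
        if self.sensitivity_offset < 0:
            raise ValidationError("sensitivity_offset must be non-negative")
        if self.bloom_amplitude < 0 or self.sediment_amplitude < 0:
            raise ValidationError("patch amplitudes must be non-negative")
        if not 0 <= self.cloud_fraction < 1:
            raise ValidationError("cloud_fraction must be in [0, 1)")

    def resolved_sensor(self) -> SensorSpec:
        s = self.sensor
        return get_sensor(s) if isinstance(s, str) else s


def _disk_mask(shape, row, col, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2


def generate_scene_pair(config: SceneGenConfig) -> ScenePair:
    """Generate one low/high scene pair with planted truth."""
    shape = tuple(config.grid_shape)
    for r, c, rad in config.bloom_patches + config.sediment_patches:
        if not (0 <= r - rad and r + rad < shape[0]
                and 0 <= c - rad and c + rad < shape[1]):
            raise ValidationError(
                f"patch (row={r}, col={c}, radius={rad}) exceeds grid {shape}"
            )
    sensor = config.resolved_sensor()
    rng = np.random.default_rng(config.seed)

    red0, nir0, swir0 = config.background
    red = np.full(shape, red0) + rng.normal(0, config.noise_sigma, shape)
    nir = np.full(shape, nir0) + rng.normal(0, config.noise_sigma, shape)
    swir = np.full(shape, swir0) + rng.normal(0, config.noise_sigma, shape)

    truth = np.zeros(shape, dtype=bool)
    for r, c, rad in config.bloom_patches:
        disk = _disk_mask(shape, r, c, rad)
        nir = np.where(disk, nir + config.bloom_amplitude, nir)
        if config.bloom_amplitude > 0:
            truth |= disk
    for r, c, rad in config.sediment_patches:
        disk = _disk_mask(shape, r, c, rad)
        nir = np.where(disk, nir + config.sediment_amplitude, nir)

    water = np.ones(shape, dtype=bool)
    water[:, : config.coast_px] = False

    cloud = np.zeros(shape, dtype=bool)
    if config.cloud_fraction > 0:
        block = max(8, min(shape) // 8)
        target = config.cloud_fraction * shape[0] * shape[1]
        while cloud.sum() < target:
            r0 = int(rng.integers(0, shape[0] - block))
            c0 = int(rng.integers(0, shape[1] - block))
            cloud[r0:r0 + block, c0:c0 + block] = True

    truth &= water

    def make(level, nir_grid):
        return Scene(date=config.date, level=level, sensor=sensor,
                     red=red.copy(), nir=nir_grid, swir=swir.copy(),
                     water_mask=water.copy(), cloud_mask=cloud.copy())

    low = make(LOW_SENSITIVITY, nir.copy())
    high = make(HIGH_SENSITIVITY, nir + config.sensitivity_offset)
    return ScenePair(low=low, high=high, truth_mask=truth)


def generate_pair_series(
    base: SceneGenConfig,
    dates: list[_dt.date],
    bloom_dates: set[_dt.date] | None = None,
    seed: int = 0,
) -> list[ScenePair]:
    """One pair per date; bloom patches present only on ``bloom_dates``.

    Sediment and clouds appear every day, so non-bloom days exercise the
    false-positive phenomenology.  Per-day seeds derive from ``seed``.
    """
    bloom_dates = set() if bloom_dates is None else set(bloom_dates)
    pairs = []
    for i, date in enumerate(dates):
        amp = base.bloom_amplitude if date in bloom_dates else 0.0
        cfg = dataclasses.replace(base, date=date, bloom_amplitude=amp,
                                  seed=(seed * 100003 + i) % (2 ** 31))
        pairs.append(generate_scene_pair(cfg))
    return pairs


@dataclasses.dataclass(frozen=True)
class SeriesGenConfig:
    """Design of the synthetic monthly bloom-area series.

    Defaults emulate a two-decade coastal record: a stable baseline with an
    upward trend starting in year 17 (≙ 2017 for a 2000 start), the default
    seasonal vector, and seasonal-MA noise at σ = 0.05 km².
    """

    n_years: int = 22
    baseline: float = 0.30
    break_year: int = 17
    slope_after: float = 0.05  # km² per year after the breakpoint
    seasonal_factors: tuple[float, ...] = DEFAULT_SEASONAL_FACTORS
    noise_params: SarimaParams = SarimaParams(0.0, -0.217, 0.689, 0.0025)
    start: str = "2000-01-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 4:
            raise ValidationError("n_years must be at least 4")
        sf = np.asarray(self.seasonal_factors, float)
        if sf.shape != (12,):
            raise ValidationError("seasonal_factors must have length 12")
        if abs(sf.sum()) > 1e-9:
            raise ValidationError("seasonal_factors must sum to zero")


def generate_monthly_series(config: SeriesGenConfig) -> AreaSeries:
    """baseline + piecewise-linear trend + seasonality + MA noise, floored at 0."""
    n = config.n_years * 12
    t = np.arange(n)
    years = t / 12.0
    trend = config.slope_after * np.maximum(0.0, years - config.break_year)
    seasonal = np.asarray(config.seasonal_factors)[t % 12]

    p = config.noise_params
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, np.sqrt(p.sigma2), size=n + 13)
    c0, c1, c12, c13 = expand_ma(p)
    noise = (c0 * eps[13:] + c1 * eps[12:-1] + c12 * eps[1:-12]
             + c13 * eps[:-13])

    values = np.maximum(0.0, config.baseline + trend + seasonal + noise)
    index = pd.date_range(config.start, periods=n, freq="MS")
    return AreaSeries(pd.Series(values, index=index), cadence="monthly")


#: Per-driver (baseline, coupling to area, noise sd).  Signs: warm water
#: promotes blooms; wind mixing and high pressure suppress them; dense blooms
#: deplete oxygen; petroleum hydrocarbons accompany blooms.
DEFAULT_DRIVER_EFFECTS: dict[str, tuple[float, float, float]] = {
    "sst": (14.0, 8.0, 1.0),
    "wind_speed": (5.0, -3.0, 0.5),
    "pressure": (1015.0, -10.0, 2.0),
    "DO": (8.0, -2.0, 0.3),
    "petroleum": (0.02, 0.02, 0.003),
    "din_dip": (20.0, 15.0, 3.0),
    "cod": (1.5, 1.0, 0.3),
}

_MET_DRIVERS = ("sst", "wind_speed", "pressure")


def generate_driver_tables(
    series: AreaSeries,
    effects: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    noise_scale: float = 1.0,
    wq_every_months: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Meteorology and water-quality tables coupled to a monthly area series.

    Each driver is ``base + coef * area + noise_scale * sd * N(0,1)``.
    Returns (meteorology df, water-quality df); water quality is sampled every
    ``wq_every_months`` months, mimicking sparse station campaigns.
    """
    effects = DEFAULT_DRIVER_EFFECTS if effects is None else effects
    rng = np.random.default_rng(seed)
    area = series.areas
    dates = series.dates

    cols = {"date": dates.strftime("%Y-%m-%d")}
    for name, (base, coef, sd) in effects.items():
        cols[name] = (base + coef * area
                      + noise_scale * sd * rng.standard_normal(len(area)))
    full = pd.DataFrame(cols)

    met = full[["date", *(d for d in _MET_DRIVERS if d in effects)]].copy()
    wq_cols = [d for d in effects if d not in _MET_DRIVERS]
    wq = full.iloc[::wq_every_months][["date", *wq_cols]].reset_index(drop=True)
    return met, wq
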