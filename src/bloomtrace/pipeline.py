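"""End-to-end orchestration: scenes → STMW areas → series → decomposition →
SARIMA → association report, from one config.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same config and seed reproduces every CSV byte for byte.  A stage that fails
aborts the run with the stage name; a stage whose input is legitimately
degenerate (e.g. an all-zero area series after suppression) is recorded with
a diagnostic instead of crashing.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path

import pandas as pd
import yaml

from . import bloom_series, sarima_model, stmw, synthetic_data
from .assoc_stats import associate, ols_report
from .bloom_extract import DEFAULT_GRID_STEP, quantize
from .errors import (
    BloomtraceError,
    DegenerateSeriesError,
    StageError,
    UndefinedStatisticError,
    ValidationError,
)
from .sensor_scene import erode_water_mask, get_sensor


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    sensor: str = "s2-like"
    threshold: float = 0.045
    min_area: float = 0.7
    ma_window: int = 7
    coastal_buffer_px: int = 2
    match_window_days: int = 7
    sarima_order: tuple = ((0, 0, 1), (0, 1, 1, 12))
    seed: int = 0
    out_dir: str = "bloomtrace_out"
    # synthetic-input design
    n_scene_days: int = 30
    scene_start: str = "2021-06-01"
    bloom_day_stride: int = 3  # every stride-th day carries a real bloom
    bloom_amplitude: float = 0.08
    n_years: int = 22
    series_source: str = "simulated"  # or "stmw": monthly means of STMW areas

    def __post_init__(self):
        if abs(quantize(self.threshold, DEFAULT_GRID_STEP) - self.threshold) > 1e-9:
            raise ValidationError(
                f"threshold {self.threshold} is not on the "
                f"{DEFAULT_GRID_STEP} grid"
            )
        if self.series_source not in ("simulated", "stmw"):
            raise ValidationError("series_source must be 'simulated' or 'stmw'")
        get_sensor(self.sensor)  # raises for unknown names

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sarima_order" in raw:
            raw["sarima_order"] = tuple(tuple(x) for x in raw["sarima_order"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a report of per-stage records and outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, dict] = {}

    def record(stage, **info):
        report[stage] = info

    # --- scenes -----------------------------------------------------------
    try:
        start = _dt.date.fromisoformat(config.scene_start)
        dates = [start + _dt.timedelta(days=i)
                 for i in range(config.n_scene_days)]
        bloom_dates = {d for i, d in enumerate(dates)
                       if i % config.bloom_day_stride == 0}
        base = synthetic_data.SceneGenConfig(
            sensor=config.sensor, bloom_amplitude=config.bloom_amplitude)
        pairs = synthetic_data.generate_pair_series(
            base, dates, bloom_dates, seed=config.seed)
        for pair in pairs:
            for scene in (pair.low, pair.high):
                scene.water_mask = erode_water_mask(
                    scene.water_mask, config.coastal_buffer_px)
        record("scenes", records=len(pairs), bloom_days=len(bloom_dates))
    except BloomtraceError as exc:
        raise StageError("scenes", str(exc)) from exc

    # --- stmw -------------------------------------------------------------
    try:
        sres = stmw.stmw_series(pairs, config.threshold, config.min_area)
        daily = pd.DataFrame({
            "date": [r.date.isoformat() for r in sres.results],
            "flagged": [int(r.flagged) for r in sres.results],
            "area_km2": [r.area for r in sres.results],
            "low_area_km2": [r.low_area for r in sres.results],
            "high_area_km2": [r.high_area for r in sres.results],
        })
        daily_path = out / "stmw_daily.csv"
        daily.to_csv(daily_path, index=False)
        record("stmw", records=len(daily), flagged=sres.n_flagged,
               suppressed=sres.n_suppressed, output=str(daily_path))
    except BloomtraceError as exc:
        raise StageError("stmw", str(exc)) from exc

    # --- series -----------------------------------------------------------
    try:
        daily_series = bloom_series.AreaSeries.from_pairs(
            [(r.date, r.area) for r in sres.results])
        smooth = bloom_series.moving_average(daily_series, config.ma_window)
        smooth.to_csv(out / "stmw_daily_ma.csv")
        if config.series_source == "simulated":
            monthly = synthetic_data.generate_monthly_series(
                synthetic_data.SeriesGenConfig(
                    n_years=config.n_years, seed=config.seed))
        else:
            monthly = bloom_series.monthly_mean(daily_series)
        monthly_path = out / "monthly_area.csv"
        monthly.to_csv(monthly_path)
        record("series", records=len(monthly), output=str(monthly_path))
    except BloomtraceError as exc:
        raise StageError("series", str(exc)) from exc

    # --- decomposition ----------------------------------------------------
    try:
        decomp = bloom_series.decompose_additive(monthly)
        pd.DataFrame({
            "month": range(1, 13),
            "seasonal_factor": decomp.seasonal_factors.to_numpy(),
        }).to_csv(out / "seasonal_factors.csv", index=False)
        pd.DataFrame({
            "date": decomp.observed.index.strftime("%Y-%m-%d"),
            "observed": decomp.observed.to_numpy(),
            "trend": decomp.trend.to_numpy(),
            "seasonal": decomp.seasonal.to_numpy(),
            "adjusted": decomp.adjusted.to_numpy(),
            "irregular": decomp.irregular.to_numpy(),
        }).to_csv(out / "decomposition.csv", index=False)
        mx_m, mx, mn_m, mn = bloom_series.seasonal_extremes(decomp)
        record("decompose", records=len(decomp.observed),
               max_month=mx_m, max_sf=mx, min_month=mn_m, min_sf=mn)
    except (DegenerateSeriesError, ValidationError) as exc:
        decomp = None
        record("decompose", records=0, diagnostic=str(exc))
    except BloomtraceError as exc:
        raise StageError("decompose", str(exc)) from exc

    # --- sarima -----------------------------------------------------------
    try:
        fit = sarima_model.fit(monthly)
        fit.summary_frame().to_csv(out / "sarima_fit.csv", index=False)
        state = sarima_model.innovations(monthly, fit.params)
        fc = sarima_model.forecast_path(fit, state, horizon=12)
        idx = pd.date_range(monthly.dates[-1] + pd.offsets.MonthBegin(),
                            periods=12, freq="MS")
        pd.DataFrame({"date": idx.strftime("%Y-%m-%d"),
                      "forecast_km2": fc}).to_csv(
            out / "sarima_forecast.csv", index=False)
        record("sarima", records=fit.n_obs,
               alpha0=fit.params.alpha0, theta=fit.params.theta,
               Theta=fit.params.Theta)
    except (DegenerateSeriesError, ValidationError) as exc:
        record("sarima", records=0, diagnostic=str(exc))
    except BloomtraceError as exc:
        raise StageError("sarima", str(exc)) from exc

    # --- association ------------------------------------------------------
    try:
        met, wq = synthetic_data.generate_driver_tables(
            monthly, seed=config.seed)
        met.to_csv(out / "meteorology.csv", index=False)
        wq.to_csv(out / "water_quality.csv", index=False)
        rows = []
        for col in met.columns.drop("date"):
            res = associate(met[col].to_numpy(), monthly.areas)
            rows.append({"driver": col, "pearson_r2": res.pearson_r2,
                         "spearman_rho": res.spearman_rho, "n": res.n})
        pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
        reg = ols_report(monthly.areas,
                         met.drop(columns="date").astype(float))
        reg.table.to_csv(out / "regression.csv")
        record("assoc", records=len(rows), output=str(out / "correlations.csv"))
    except (UndefinedStatisticError, ValidationError) as exc:
        record("assoc", records=0, diagnostic=str(exc))
    except BloomtraceError as exc:
        raise StageError("assoc", str(exc)) from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=1,
                                                    default=str))
    return report
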