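"""SARIMA (0,0,1)(0,1,1)₁₂ modelling of monthly bloom area.

The model seasonally differences the monthly series once at lag 12 and puts
a multiplicative MA structure plus an intercept (drift) on the differenced
series:

    (1 - L^12) y_t = α₀ + (1 + θ L)(1 + Θ L^12) ε_t,   ε_t ~ WN(0, σ²)

Expanding the MA product gives innovation lags {0, 1, 12, 13} with
coefficients (1, θ, Θ, θΘ), hence the explicit forecast recursion

    y_t = α₀ + y_{t-12} + ε_t + θ ε_{t-1} + Θ ε_{t-12} + θΘ ε_{t-13}.

Estimation maximizes the exact Gaussian likelihood (state-space innovations
filter) on the lag-12-differenced series with the three free parameters
(α₀, θ, Θ) plus σ², under invertibility of both MA factors.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .bloom_series import AreaSeries, _check_contiguous_monthly
from .errors import DegenerateSeriesError, FitConvergenceError, ValidationError

SEASONAL_PERIOD = 12
#: earliest innovation lag entering the recursion
MAX_EPS_LAG = 13

PARAM_NAMES = ("alpha0", "theta", "Theta", "sigma2")


@dataclasses.dataclass(frozen=True)
class SarimaParams:
    """(α₀, θ, Θ, σ²) of the seasonal MA model."""

    alpha0: float
    theta: float
    Theta: float
    sigma2: float

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValidationError("sigma2 must be non-negative")


@dataclasses.dataclass
class SarimaFit:
    """Estimates with standard errors, t statistics and two-sided p-values."""

    params: SarimaParams
    std_errors: dict[str, float]
    t_values: dict[str, float]
    significance: dict[str, float]
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        """Report table: parameter, estimate, std error, t, significance."""
        est = dataclasses.asdict(self.params)
        rows = []
        for name in PARAM_NAMES:
            rows.append({
                "parameter": name,
                "estimate": est[name],
                "std_error": self.std_errors.get(name, np.nan),
                "t": self.t_values.get(name, np.nan),
                "significance": self.significance.get(name, np.nan),
            })
        return pd.DataFrame(rows)


@dataclasses.dataclass
class RecursionState:
    """Aligned past observations y_t and innovations ε_t, oldest first."""

    y_history: np.ndarray
    eps_history: np.ndarray

    def __post_init__(self):
        self.y_history = np.asarray(self.y_history, dtype=float)
        self.eps_history = np.asarray(self.eps_history, dtype=float)


def expand_ma(params: SarimaParams) -> tuple[float, float, float, float]:
    """Coefficients of (1 + θL)(1 + ΘL¹²) at innovation lags {0, 1, 12, 13}."""
    return (1.0, params.theta, params.Theta, params.theta * params.Theta)


def forecast_one(state: RecursionState, params: SarimaParams) -> float:
    """One-step-ahead point forecast (future innovation at its mean, zero)."""
    if len(state.y_history) < SEASONAL_PERIOD:
        raise ValidationError(
            f"need y at seasonal lag {SEASONAL_PERIOD}: only "
            f"{len(state.y_history)} past values"
        )
    if len(state.eps_history) < MAX_EPS_LAG:
        raise ValidationError(
            f"need innovations back to lag {MAX_EPS_LAG}: only "
            f"{len(state.eps_history)} past innovations"
        )
    y = state.y_history
    e = state.eps_history
    _, c1, c12, c13 = expand_ma(params)
    return float(params.alpha0 + y[-12] + c1 * e[-1] + c12 * e[-12]
                 + c13 * e[-13])


def simulate(
    params: SarimaParams,
    n_months: int,
    seed: int,
    init: np.ndarray | None = None,
    start: str = "2000-01-01",
) -> AreaSeries:
    """Simulate the recursion with Gaussian innovations.

    ``init`` supplies the first 12 values of the series (default zeros);
    pre-sample innovations are zero.  Deterministic for a fixed seed.
    Negative values are kept as-is — the model is unconstrained.
    """
    if n_months <= MAX_EPS_LAG:
        raise ValidationError(f"n_months must exceed {MAX_EPS_LAG}")
    init = np.zeros(SEASONAL_PERIOD) if init is None else np.asarray(init, float)
    if init.shape != (SEASONAL_PERIOD,):
        raise ValidationError(f"init must have length {SEASONAL_PERIOD}")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(params.sigma2), size=n_months)
    _, c1, c12, c13 = expand_ma(params)

    y = np.empty(n_months)
    y[:SEASONAL_PERIOD] = init

    def e(t: int) -> float:
        return eps[t] if t >= 0 else 0.0

    for t in range(SEASONAL_PERIOD, n_months):
        y[t] = (params.alpha0 + y[t - 12] + e(t) + c1 * e(t - 1)
                + c12 * e(t - 12) + c13 * e(t - 13))
    index = pd.date_range(start, periods=n_months, freq="MS")
    return AreaSeries(pd.Series(y, index=index), cadence="monthly",
                      allow_negative=True)


def seasonal_difference(series: AreaSeries) -> np.ndarray:
    """z_t = y_t − y_{t−12} on a gap-free monthly series."""
    _check_contiguous_monthly(series)
    y = series.areas
    return y[SEASONAL_PERIOD:] - y[:-SEASONAL_PERIOD]


def fit(series: AreaSeries) -> SarimaFit:
    """Fit SARIMA (0,0,1)(0,1,1)₁₂ with intercept by exact Gaussian MLE.

    The series is seasonally differenced once at lag 12 and the resulting
    intercept + MA(1) + seasonal-MA(1) model is estimated by state-space
    maximum likelihood under invertibility.  Standard errors come from the
    inverse observed information; p-values are two-sided normal.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    if len(series) < 4 * SEASONAL_PERIOD:
        raise ValidationError("need at least 4 years of monthly data")
    if series.entries.isna().any():
        raise ValidationError("series has gaps; fill them before fitting")
    z = seasonal_difference(series)
    if np.ptp(z - z.mean()) < 1e-12:
        raise DegenerateSeriesError(
            "seasonally differenced series is constant: innovation variance "
            "is zero and the MA coefficients are unidentified"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(z, order=(0, 0, 1),
                        seasonal_order=(0, 0, 1, SEASONAL_PERIOD),
                        trend="c", enforce_invertibility=True)
        res = model.fit(disp=0, maxiter=500)
        if not res.mle_retvals.get("converged", True):
            # L-BFGS occasionally stops on a line-search failure with the
            # gradient already tiny; polish with a simplex restart
            res = model.fit(disp=0, method="nm", maxiter=5000,
                            start_params=res.params)
    if not res.mle_retvals.get("converged", True):
        raise FitConvergenceError("SARIMA likelihood maximization did not "
                                  "converge", last_params=res.params)
    names = {"intercept": "alpha0", "ma.L1": "theta",
             "ma.S.L12": "Theta", "sigma2": "sigma2"}
    est, se, pv = {}, {}, {}
    for raw, ours in names.items():
        i = list(res.model.param_names).index(raw)
        est[ours] = float(res.params[i])
        se[ours] = float(res.bse[i])
        pv[ours] = float(res.pvalues[i])
    params = SarimaParams(est["alpha0"], est["theta"], est["Theta"],
                          est["sigma2"])
    t_values = {k: est[k] / se[k] if se[k] > 0 else np.inf for k in est}
    return SarimaFit(params=params, std_errors=se, t_values=t_values,
                     significance=pv, n_obs=len(z))


def innovations(series: AreaSeries, params: SarimaParams) -> RecursionState:
    """Recover conditional innovations from an observed series.

    Runs the recursion forward with pre-sample innovations at zero:
    ε_t = y_t − α₀ − y_{t−12} − θ ε_{t−1} − Θ ε_{t−12} − θΘ ε_{t−13}.
    """
    _check_contiguous_monthly(series)
    y = series.areas
    n = len(y)
    if n < 2 * SEASONAL_PERIOD:
        raise ValidationError("need at least 24 months to recover innovations")
    _, c1, c12, c13 = expand_ma(params)
    eps = np.zeros(n)

    def e(t: int) -> float:
        return eps[t] if t >= 0 else 0.0

    for t in range(SEASONAL_PERIOD, n):
        eps[t] = (y[t] - params.alpha0 - y[t - 12]
                  - c1 * e(t - 1) - c12 * e(t - 12) - c13 * e(t - 13))
    return RecursionState(y_history=y, eps_history=eps)


def forecast_path(
    fit_result: SarimaFit | SarimaParams,
    state: RecursionState,
    horizon: int,
    clamp_at_zero: bool = False,
) -> np.ndarray:
    """Iterated point forecasts with future innovations at zero.

    Beyond lag 13 the path is purely seasonal-plus-drift: each forecast equals
    the value one year earlier plus α₀.  Negative forecasts are kept unless
    ``clamp_at_zero`` (presentation only; the model is unconstrained).
    """
    if horizon < 1:
        raise ValidationError("horizon must be at least 1")
    params = fit_result.params if isinstance(fit_result, SarimaFit) else fit_result
    y = list(state.y_history)
    e = list(state.eps_history)
    out = []
    for _ in range(horizon):
        step = forecast_one(RecursionState(y, e), params)
        out.append(step)
        y.append(step)
        e.append(0.0)
    out = np.array(out)
    return np.maximum(out, 0.0) if clamp_at_zero else out
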