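"""Association statistics between bloom area and environmental drivers.

Two report shapes: a correlation table (Pearson r² and Spearman ρ per
driver) and an OLS regression table (coefficient, standard error, t,
two-sided p per predictor).  Either a single multivariate fit (default) or
one fit per predictor can be produced.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, UndefinedStatisticError, ValidationError


@dataclasses.dataclass
class AssocResult:
    pearson_r2: float
    spearman_rho: float
    n: int


@dataclasses.dataclass
class RegressionResult:
    """Per-predictor OLS report (rows: coefficient, std_err, t, p)."""

    table: pd.DataFrame
    n: int
    model: str
    degenerate: bool = False  # zero residual variance: SEs are not meaningful


def associate(x, y) -> AssocResult:
    """Pearson r² and Spearman ρ (average ranks) on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return AssocResult(pearson_r2=float(r ** 2), spearman_rho=float(rho),
                       n=len(x))


def _find_dependent_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (collinearity offenders)."""
    A = X.to_numpy(dtype=float)
    full = np.linalg.matrix_rank(A)
    offenders = []
    for j, col in enumerate(X.columns):
        reduced = np.delete(A, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            offenders.append(col)
    return offenders


def ols_report(
    y, X: pd.DataFrame, per_factor: bool = False
) -> RegressionResult | list[RegressionResult]:
    """OLS with intercept; report coefficient, std error, t, two-sided p.

    ``per_factor=True`` fits one single-predictor model per column instead of
    a joint multivariate model.  Exact fits (zero residual variance) are
    flagged degenerate rather than reporting meaningless zero SEs as sound.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if per_factor:
        return [ols_report(y, X[[c]], per_factor=False) for c in X.columns]
    if len(y) != len(X):
        raise ValidationError("y and X must have equal length")
    if len(y) <= X.shape[1] + 1:
        raise ValidationError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy(dtype=float)) < design.shape[1]:
        offenders = _find_dependent_columns(design.drop(columns="const"))
        raise CollinearityError(
            f"rank-deficient design; dependent columns: {offenders}",
            columns=offenders,
        )
    res = sm.OLS(y, design).fit()
    table = pd.DataFrame({
        "coefficient": res.params,
        "std_err": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    })
    degenerate = bool(res.ssr <= max(1e-12 * float(y @ y), 1e-300))
    label = "multivariate" if X.shape[1] > 1 else f"univariate:{X.columns[0]}"
    return RegressionResult(table=table, n=len(y), model=label,
                            degenerate=degenerate)
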