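"""Cointegration bounds test and residual/series diagnostics.

The bounds F-test regresses Δy on an intercept, the lagged levels of the
outcome and all regressors, and the short-run differences implied by the
ARDL specification, then tests joint nullity of the k+1 level terms.  The
statistic has a non-standard null distribution that depends on the
integration order of the regressors, so it is compared against a pair of
critical bounds: below the lower (all-I(0)) bound the no-cointegration null
stands, above the upper (all-I(1)) bound it is rejected, in between the test
is inconclusive.

Residual diagnostics are Lagrange-multiplier auxiliary regressions in F
form: Breusch-Godfrey for serial correlation and Breusch-Pagan (levels of
the regressors) for heteroscedasticity.  The unit-root pre-check is an
augmented Dickey-Fuller regression with SIC lag selection, used to certify
that no series is integrated of order two.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._critical_values import BOUNDS_K5, DF_PROBS, DF_QUANTILES
from .ardl import ARDLSpec, _ols
from .errors import (
    ConfigurationError,
    DegeneracyError,
    EstimationError,
    SizingError,
)
from .panel import MacroPanel, OUTCOMES, REGRESSORS

__all__ = [
    "BoundsResult",
    "DiagnosticResult",
    "UnitRootResult",
    "CorrelationScreen",
    "bounds_f_test",
    "serial_correlation_test",
    "heteroscedasticity_test",
    "unit_root_test",
    "correlation_screen",
]

SIGNIFICANCE_LEVELS = (0.10, 0.05, 0.01)


@dataclass(frozen=True)
class BoundsResult:
    """Outcome of the cointegration bounds F-test (k = 5, intercept case)."""

    f_stat: float
    k: int
    case: str
    bounds: dict[float, tuple[float, float]]
    decisions: dict[float, str]
    nobs: int

    def decision(self, level: float = 0.05) -> str:
        return self.decisions[level]

    def stars(self) -> str:
        from .ardl import star_labels

        for level, label in ((0.01, "***"), (0.05, "**"), (0.10, "*")):
            if self.decisions[level] == "cointegration":
                return label
        return ""

    def __str__(self) -> str:
        return f"{self.f_stat:.3f}{self.stars()}"


@dataclass(frozen=True)
class DiagnosticResult:
    """A residual diagnostic in 'statistic [p-value]' form."""

    test_name: str
    statistic: float
    p_value: float
    lag_order: int
    df: tuple[int, int]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ConfigurationError(f"p-value outside [0, 1]: {self.p_value}")

    def __str__(self) -> str:
        return f"{self.statistic:.4f} [{self.p_value:.4f}]"


@dataclass(frozen=True)
class UnitRootResult:
    """ADF verdicts for a series' level and first difference."""

    test_name: str
    statistic: float
    p_value: float
    lag_order: int
    trend: str
    critical_values: dict[float, float] = field(repr=False)
    diff_statistic: float = float("nan")
    diff_p_value: float = float("nan")
    integration_order: str = ""

    def __str__(self) -> str:
        return f"{self.statistic:.4f} [{self.p_value:.4f}] ({self.integration_order})"


@dataclass(frozen=True)
class CorrelationScreen:
    """Pairwise correlations among the regressors plus collinearity flags."""

    matrix: pd.DataFrame
    flags: list[tuple[str, str, float]]
    threshold: float


def _bounds_design(
    w: pd.DataFrame, spec: ARDLSpec, outcome: str
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    y = w[outcome]
    dy = y.diff()
    cols: dict[str, pd.Series] = {}
    level_names = [f"{outcome}.L1"]
    cols[f"{outcome}.L1"] = y.shift(1)
    for r in REGRESSORS:
        level_names.append(f"{r}.L1")
        cols[f"{r}.L1"] = w[r].shift(1)
    for m in range(1, spec.p):
        cols[f"Δ{outcome}.L{m}"] = dy.shift(m)
    for r in REGRESSORS:
        dx = w[r].diff()
        for m in range(max(spec.q[r], 1)):
            cols[f"Δ{r}.L{m}"] = dx.shift(m)
    X = pd.DataFrame(cols)
    mask = X.notna().all(axis=1) & dy.notna()
    X = X.loc[mask]
    X.insert(0, "const", 1.0)
    return X, dy.loc[mask], level_names


def bounds_f_test(
    panel: MacroPanel | pd.DataFrame, spec: ARDLSpec, outcome: str
) -> BoundsResult:
    """F-test of joint nullity of the lagged level terms in the unrestricted ECM."""
    w = panel.working() if isinstance(panel, MacroPanel) else panel
    X, dy, level_names = _bounds_design(w, spec, outcome)
    n, k_u = X.shape
    n_restr = len(level_names)
    if n - k_u < 1:
        raise SizingError(
            f"unrestricted bounds regression has {k_u} parameters but only {n} rows"
        )
    Xa = X.to_numpy(float)
    ya = dy.to_numpy(float)
    if np.linalg.matrix_rank(Xa) < k_u:
        raise EstimationError("unrestricted bounds design is singular")
    _, ssr_u = _ols(Xa, ya)
    keep = [c for c in X.columns if c not in level_names]
    _, ssr_r = _ols(X[keep].to_numpy(float), ya)
    if ssr_u <= 0:
        raise EstimationError("perfect fit in unrestricted bounds regression")
    f_stat = ((ssr_r - ssr_u) / n_restr) / (ssr_u / (n - k_u))
    decisions = {}
    for level in SIGNIFICANCE_LEVELS:
        lo, hi = BOUNDS_K5[level]
        if f_stat > hi:
            decisions[level] = "cointegration"
        elif f_stat < lo:
            decisions[level] = "no-cointegration"
        else:
            decisions[level] = "inconclusive"
    return BoundsResult(
        f_stat=float(f_stat),
        k=len(REGRESSORS),
        case="intercept, no trend",
        bounds=dict(BOUNDS_K5),
        decisions=decisions,
        nobs=n,
    )


def _aligned_arrays(resid, design) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(resid, dtype=float).ravel()
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(e) != X.shape[0]:
        raise SizingError(
            f"residuals ({len(e)}) and design rows ({X.shape[0]}) are not aligned"
        )
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(e)), X])
    return e, X


def serial_correlation_test(resid, design, lag_order: int = 2) -> DiagnosticResult:
    """Breusch-Godfrey LM test (F form) for residual autocorrelation.

    Auxiliary regression of the residuals on the original regressors plus
    ``lag_order`` lagged residuals (pre-sample lags set to zero); the F
    statistic tests joint nullity of the lagged-residual coefficients.
    """
    e, X = _aligned_arrays(resid, design)
    n, k = X.shape
    if lag_order < 1:
        raise ConfigurationError("lag_order must be >= 1")
    if lag_order >= n:
        raise SizingError(f"lag_order {lag_order} >= residual length {n}")
    lags = np.zeros((n, lag_order))
    for j in range(1, lag_order + 1):
        lags[j:, j - 1] = e[:-j]
    _, ssr0 = _ols(X, e)
    Xa = np.column_stack([X, lags])
    df2 = n - Xa.shape[1]
    if df2 < 1:
        raise SizingError("no residual degrees of freedom in auxiliary regression")
    _, ssr1 = _ols(Xa, e)
    f = ((ssr0 - ssr1) / lag_order) / (ssr1 / df2)
    p = float(stats.f.sf(f, lag_order, df2))
    return DiagnosticResult("serial_correlation", float(f), p, lag_order, (lag_order, df2))


def heteroscedasticity_test(resid, design) -> DiagnosticResult:
    """Breusch-Pagan LM test (F form): squared residuals on the regressors."""
    e, X = _aligned_arrays(resid, design)
    n, k = X.shape
    u = e**2
    if np.ptp(u) < 1e-14 * max(1.0, float(np.abs(u).max())):
        raise DegeneracyError("squared residuals are constant; test undefined")
    if k < 2:
        raise ConfigurationError("design must contain at least one non-constant column")
    df2 = n - k
    if df2 < 1:
        raise SizingError("no residual degrees of freedom in auxiliary regression")
    _, ssr1 = _ols(X, u)
    ssr0 = float(((u - u.mean()) ** 2).sum())
    f = ((ssr0 - ssr1) / (k - 1)) / (ssr1 / df2)
    p = float(stats.f.sf(f, k - 1, df2))
    return DiagnosticResult("heteroscedasticity", float(f), p, 0, (k - 1, df2))


def _df_p_value(tau: float, trend: str) -> float:
    qs = np.asarray(DF_QUANTILES[trend])
    ps = np.asarray(DF_PROBS)
    return float(np.clip(np.interp(tau, qs, ps, left=ps[0] / 2, right=1 - (1 - ps[-1]) / 2),
                         1e-4, 1 - 1e-4))


def _adf_tau(x: np.ndarray, k: int, offset: int, trend: str) -> tuple[float, float]:
    """Dickey-Fuller t-statistic with k lagged differences, dropping
    ``offset`` initial difference rows; returns (tau, ssr-based SIC)."""
    dx = np.diff(x)
    rows = np.arange(offset, len(dx))
    cols = [np.ones(len(rows)), x[rows]]
    if trend == "ct":
        cols.append(rows.astype(float))
    for j in range(1, k + 1):
        cols.append(dx[rows - j])
    X = np.column_stack(cols)
    y = dx[rows]
    beta, ssr = _ols(X, y)
    nn, kk = X.shape
    sic = nn * np.log(max(ssr, 1e-300) / nn) + kk * np.log(nn)
    sigma2 = ssr / (nn - kk)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    return float(beta[1] / se), float(sic)


def _adf_stat(x: np.ndarray, max_lag: int, trend: str) -> tuple[float, int]:
    """ADF t-statistic; lag order by SIC on a common sample, statistic
    refitted at the chosen lag on the full available sample."""
    if len(x) - 1 - max_lag < 8:
        raise SizingError(f"series too short for ADF with max_lag={max_lag}")
    best = None
    for k in range(max_lag + 1):
        _, sic = _adf_tau(x, k, max_lag, trend)
        if best is None or sic < best[1]:
            best = (k, sic)
    k = best[0]
    tau, _ = _adf_tau(x, k, k, trend)
    return tau, k


def unit_root_test(series, max_lag: int = 4, trend: str = "c") -> UnitRootResult:
    """ADF unit-root test on a series and its first difference.

    Reports an approximate p-value by interpolation on embedded Monte-Carlo
    null quantiles and an integration-order verdict at the 5% level:
    ``I(0)`` if the level rejects, ``I(1)`` if only the difference rejects,
    ``I(2)+`` otherwise.
    """
    if trend not in ("c", "ct"):
        raise ConfigurationError(f"trend must be 'c' or 'ct', got {trend!r}")
    x = np.asarray(series, dtype=float).ravel()
    if len(x) <= max_lag + 3:
        raise SizingError(f"series length {len(x)} must exceed max_lag + 3 = {max_lag + 3}")
    if np.ptp(x) < 1e-14 * max(1.0, float(np.abs(x).max())):
        raise DegeneracyError("constant series has no unit-root behaviour to test")
    tau, k = _adf_stat(x, max_lag, trend)
    tau_d, _ = _adf_stat(np.diff(x), max_lag, trend)
    crit = {
        level: float(np.interp(level, DF_PROBS, DF_QUANTILES[trend]))
        for level in SIGNIFICANCE_LEVELS
    }
    p = _df_p_value(tau, trend)
    p_d = _df_p_value(tau_d, trend)
    if p < 0.05:
        order = "I(0)"
    elif p_d < 0.05:
        order = "I(1)"
    else:
        order = "I(2)+"
    return UnitRootResult(
        test_name="unit_root",
        statistic=float(tau),
        p_value=p,
        lag_order=k,
        trend=trend,
        critical_values=crit,
        diff_statistic=float(tau_d),
        diff_p_value=p_d,
        integration_order=order,
    )


def correlation_screen(
    panel: MacroPanel | pd.DataFrame, threshold: float = 0.9
) -> CorrelationScreen:
    """Pairwise Pearson correlations among the regressors (working scale)."""
    w = panel.working() if isinstance(panel, MacroPanel) else panel
    block = w[[c for c in REGRESSORS if c in w.columns]]
    if block.shape[1] < 2:
        raise ConfigurationError("need at least two regressors to screen")
    if len(block) < 3:
        raise SizingError("need at least 3 complete rows for a correlation screen")
    sds = block.std(ddof=1)
    zero_var = [c for c in block.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    if zero_var:
        raise DegeneracyError(f"zero-variance column(s): {zero_var}")
    mat = block.corr()
    flags = []
    cols = list(block.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(mat.loc[a, b])
            if abs(r) > threshold:
                flags.append((a, b, r))
    return CorrelationScreen(matrix=mat, flags=flags, threshold=threshold)
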