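"""ARDL estimation in levels and its error-correction re-parameterization.

The model for one outcome y and regressors x_1..x_k on the working scale is

    y_t = β0 + Σ_{j=1..p} α_j y_{t-j} + Σ_i Σ_{j=0..q_i} β_{ij} x_{i,t-j} + ε_t

estimated by OLS.  The fitted levels model is then rewritten *exactly* as an
error-correction model

    Δy_t = θ (y_{t-1} − a0 − Σ_i b_i x_{i,t-1})
           + Σ_{m=1..p-1} λ_m Δy_{t-m}
           + Σ_i [ β_{i0} Δx_{i,t} + Σ_{m=1..q_i-1} c_{im} Δx_{i,t-m} ] + ε_t

with  θ = −(1 − Σ_j α_j),  b_i = (Σ_j β_{ij}) / (1 − Σ_j α_j),
a0 = β0 / (1 − Σ_j α_j),  λ_m = −Σ_{j>m} α_j,  c_{im} = −Σ_{j>m} β_{ij}.

Because the transformation is algebraic, ECM and levels forms share fitted
values and residuals identically; standard errors of the derived quantities
come from the OLS coefficient covariance (delta method for the long-run
slopes, exact linear combinations for the short-run terms).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConfigurationError, DegeneracyError, EstimationError, SizingError
from .panel import MacroPanel, OUTCOMES, REGRESSORS

__all__ = [
    "ARDLSpec",
    "LevelsFit",
    "LongRunParams",
    "ECMFit",
    "build_design",
    "fit_levels",
    "fit_ardl",
    "select_lags",
    "to_ecm",
    "ecm_residuals",
    "star_labels",
]

#: |1 − Σα| below this means no long-run relation is identified.
DEGENERACY_TOL = 1e-8


def star_labels(p_value: float) -> str:
    """Significance stars: *** p<0.01, ** p<0.05, * p<0.10, '' otherwise."""
    if not (0.0 <= p_value <= 1.0) or math.isnan(p_value):
        raise ConfigurationError(f"p-value must lie in [0, 1], got {p_value!r}")
    if p_value < 0.01:
        return "***"
    if p_value < 0.05:
        return "**"
    if p_value < 0.10:
        return "*"
    return ""


@dataclass(frozen=True)
class ARDLSpec:
    """Lag structure of an ARDL(p, q_1..q_k) model.

    ``q`` may be a single integer (applied to every regressor) or a mapping
    regressor-name → lag order.  ``trend`` is ``"c"`` (intercept only, the
    default) or ``"ct"`` (intercept plus linear trend).
    """

    p: int = 1
    q: Mapping[str, int] | int = 0
    trend: str = "c"

    def __post_init__(self):
        if not isinstance(self.p, (int, np.integer)) or self.p < 1:
            raise ConfigurationError(f"autoregressive order p must be >= 1, got {self.p!r}")
        if isinstance(self.q, (int, np.integer)):
            qmap = {r: int(self.q) for r in REGRESSORS}
        else:
            qmap = {r: int(self.q[r]) for r in REGRESSORS if r in self.q}
            missing = [r for r in REGRESSORS if r not in qmap]
            if missing:
                raise ConfigurationError(f"q orders missing for: {missing}")
        if any(v < 0 for v in qmap.values()):
            raise ConfigurationError(f"q orders must be >= 0, got {qmap}")
        if self.trend not in ("c", "ct"):
            raise ConfigurationError(f"trend must be 'c' or 'ct', got {self.trend!r}")
        object.__setattr__(self, "q", qmap)

    @property
    def max_lag(self) -> int:
        return max(self.p, max(self.q.values()))

    @property
    def n_params(self) -> int:
        return (2 if self.trend == "ct" else 1) + self.p + sum(v + 1 for v in self.q.values())

    def min_obs(self) -> int:
        """Smallest panel length leaving at least one residual degree of freedom."""
        return self.max_lag + self.n_params + 1


def _column_order(spec: ARDLSpec, outcome: str) -> list[str]:
    cols = ["const"]
    if spec.trend == "ct":
        cols.append("trend")
    cols += [f"{outcome}.L{j}" for j in range(1, spec.p + 1)]
    for r in REGRESSORS:
        cols += [f"{r}.L{j}" for j in range(spec.q[r] + 1)]
    return cols


def build_design(
    panel: MacroPanel | pd.DataFrame, spec: ARDLSpec, outcome: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Lagged design matrix and response for the levels ARDL.

    Accepts a :class:`MacroPanel` (transformed to the working scale) or an
    already-working-scale DataFrame.  Rows with lag-induced missing values
    are dropped from the top; the column order is
    ``const [, trend], y.L1..y.Lp, x1.L0..x1.Lq1, ..., xk.L0..xk.Lqk`` with
    regressors in canonical order (health, gfc, unemployment, cons,
    corruption).
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome '{outcome}'")
    w = panel.working() if isinstance(panel, MacroPanel) else panel
    T = len(w)
    if T < spec.min_obs():
        raise SizingError(
            f"panel has {T} observations; ARDL(p={spec.p}, q={tuple(spec.q.values())}) "
            f"needs at least {spec.min_obs()}"
        )
    maxlag = spec.max_lag
    idx = w.index[maxlag:]
    data = {}
    y = w[outcome]
    for j in range(1, spec.p + 1):
        data[f"{outcome}.L{j}"] = y.shift(j)
    for r in REGRESSORS:
        for j in range(spec.q[r] + 1):
            data[f"{r}.L{j}"] = w[r].shift(j)
    X = pd.DataFrame(data).loc[idx]
    X.insert(0, "const", 1.0)
    if spec.trend == "ct":
        X.insert(1, "trend", np.arange(T, dtype=float)[maxlag:])
    X = X[_column_order(spec, outcome)]
    return X, y.loc[idx]


def _ols(Xa: np.ndarray, ya: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(Xa, ya, rcond=None)
    resid = ya - Xa @ beta
    return beta, float(resid @ resid)


def _check_rank(X: pd.DataFrame) -> None:
    Xa = X.to_numpy(float)
    _, R, piv = linalg.qr(Xa, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(Xa.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = [X.columns[i] for i in piv[rank:]]
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass(frozen=True)
class LevelsFit:
    """OLS fit of the levels ARDL."""

    spec: ARDLSpec
    outcome: str
    params: pd.Series
    cov: pd.DataFrame = field(repr=False)
    resid: pd.Series = field(repr=False)
    fitted: pd.Series = field(repr=False)
    nobs: int
    df_resid: int
    sigma2: float
    loglik: float
    aic: float
    sic: float
    design: pd.DataFrame = field(repr=False)
    response: pd.Series = field(repr=False)
    working: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def fit_levels(
    design: pd.DataFrame,
    response: pd.Series,
    spec: ARDLSpec | None = None,
    outcome: str | None = None,
    working: pd.DataFrame | None = None,
) -> LevelsFit:
    """OLS on a prepared design: estimates, classical covariance, AIC/SIC."""
    X = design if isinstance(design, pd.DataFrame) else pd.DataFrame(design)
    y = response if isinstance(response, pd.Series) else pd.Series(np.asarray(response))
    n, k = X.shape
    if n - k < 1:
        raise SizingError(f"{n} rows cannot support {k} parameters (no residual df)")
    _check_rank(X)
    Xa = X.to_numpy(float)
    ya = y.to_numpy(float)
    beta, ssr = _ols(Xa, ya)
    df = n - k
    sigma2 = ssr / df
    XtX_inv = linalg.inv(Xa.T @ Xa)
    cov = sigma2 * XtX_inv
    sigma2_ml = ssr / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2_ml) + 1.0)
    fitted = Xa @ beta
    return LevelsFit(
        spec=spec,
        outcome=outcome,
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        resid=pd.Series(ya - fitted, index=y.index),
        fitted=pd.Series(fitted, index=y.index),
        nobs=n,
        df_resid=df,
        sigma2=sigma2,
        loglik=loglik,
        aic=-2 * loglik + 2 * k,
        sic=-2 * loglik + k * math.log(n),
        design=X,
        response=y,
        working=working,
    )


def fit_ardl(panel: MacroPanel | pd.DataFrame, spec: ARDLSpec, outcome: str) -> LevelsFit:
    """Convenience wrapper: build the design and fit in one call."""
    w = panel.working() if isinstance(panel, MacroPanel) else panel
    X, y = build_design(w, spec, outcome)
    return fit_levels(X, y, spec=spec, outcome=outcome, working=w)


def select_lags(
    panel: MacroPanel | pd.DataFrame,
    outcome: str,
    p_max: int = 2,
    q_max: int = 2,
    criterion: str = "aic",
    trend: str = "c",
) -> ARDLSpec:
    """Exhaustive lag-order search on a common effective sample.

    All candidates (p, q_1..q_k) ∈ [1..p_max] × [0..q_max]^k are estimated on
    the sample that the largest candidate allows, so information criteria are
    comparable.  Ties are broken toward fewer parameters, then
    lexicographically by (p, q_1..q_k).
    """
    if p_max < 1 or q_max < 0:
        raise ConfigurationError("p_max must be >= 1 and q_max >= 0")
    if criterion not in ("aic", "sic"):
        raise ConfigurationError(f"criterion must be 'aic' or 'sic', got {criterion!r}")
    w = panel.working() if isinstance(panel, MacroPanel) else panel
    full_spec = ARDLSpec(p=p_max, q=q_max, trend=trend)
    try:
        X_full, y_full = build_design(w, full_spec, outcome)
    except SizingError as e:
        raise SizingError(f"lag grid infeasible: {e}") from e
    n = len(y_full)
    ya = y_full.to_numpy(float)
    penalty = 2.0 if criterion == "aic" else math.log(n)
    # SSR at numerical zero (exact interpolation) is treated as a perfect
    # fit; ties are then broken by parameter count, not by rounding noise.
    ssr_floor = 1e-12 * float(((ya - ya.mean()) ** 2).sum())

    best = None  # (crit, (n_params, p, q_tuple), spec)
    for p in range(1, p_max + 1):
        for q_tuple in itertools.product(range(q_max + 1), repeat=len(REGRESSORS)):
            spec = ARDLSpec(p=p, q=dict(zip(REGRESSORS, q_tuple)), trend=trend)
            cols = _column_order(spec, outcome)
            if n - len(cols) < 1:
                continue
            Xa = X_full[cols].to_numpy(float)
            _, ssr = _ols(Xa, ya)
            if ssr <= ssr_floor:
                crit = -math.inf
            else:
                crit = n * math.log(ssr / n) + penalty * len(cols)
            key = (len(cols), p, q_tuple)
            tied = best is not None and (
                crit == best[0] or abs(crit - best[0]) <= 1e-9
            )
            if best is None or (not tied and crit < best[0]) or (tied and key < best[1]):
                best = (crit, key, spec)
    if best is None:
        raise SizingError(
            f"no (p, q) candidate up to ({p_max}, {q_max}) leaves residual degrees "
            f"of freedom at T = {len(w)}"
        )
    return best[2]


@dataclass(frozen=True)
class LongRunParams:
    """Long-run (steady-state) relation y* = intercept + Σ b_i x_i."""

    outcome: str
    intercept: float
    intercept_se: float
    slopes: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    stars: dict[str, str]

    def predict(self, x_working: Mapping[str, float]) -> float:
        """Steady-state outcome (working scale) at the given regressor levels."""
        return self.intercept + sum(self.slopes[r] * float(x_working[r]) for r in REGRESSORS)


@dataclass(frozen=True)
class ECMFit:
    """Error-correction re-parameterization of a :class:`LevelsFit`.

    ``short_run`` is a tidy table with one row per Δ-term (lagged Δoutcome
    and Δregressor terms) holding coefficient, standard error, p-value and
    significance stars.
    """

    levels: LevelsFit = field(repr=False)
    theta: float
    theta_se: float
    theta_p_value: float
    long_run: LongRunParams
    short_run: pd.DataFrame = field(repr=False)
    resid: pd.Series = field(repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)

    @property
    def outcome(self) -> str:
        return self.levels.outcome

    @property
    def spec(self) -> ARDLSpec:
        return self.levels.spec


def _linear_combo_se(cov: pd.DataFrame, weights: pd.Series) -> float:
    c = weights.reindex(cov.index, fill_value=0.0).to_numpy(float)
    return float(np.sqrt(c @ cov.to_numpy(float) @ c))


def to_ecm(fit: LevelsFit) -> ECMFit:
    """Exact ECM re-parameterization with delta-method long-run inference."""
    if fit.spec is None or fit.outcome is None:
        raise ConfigurationError("fit must carry its ARDLSpec and outcome to re-parameterize")
    spec, outcome = fit.spec, fit.outcome
    if spec.trend != "c":
        raise ConfigurationError(
            "ECM re-parameterization and long-run extraction are defined for "
            "intercept-only fits (trend='c')"
        )
    params, cov = fit.params, fit.cov
    alpha = np.array([params[f"{outcome}.L{j}"] for j in range(1, spec.p + 1)])
    A = alpha.sum()
    one_minus_A = 1.0 - A
    if abs(one_minus_A) < DEGENERACY_TOL:
        raise DegeneracyError(
            f"|1 - sum(AR coefficients)| = {abs(one_minus_A):.2e} < {DEGENERACY_TOL}; "
            "no long-run relation is identified"
        )
    theta = -one_minus_A
    ar_names = [f"{outcome}.L{j}" for j in range(1, spec.p + 1)]
    theta_se = _linear_combo_se(cov, pd.Series(1.0, index=ar_names))
    theta_p = 2 * stats.t.sf(abs(theta / theta_se), df=fit.df_resid) if theta_se > 0 else float("nan")

    # Long-run slopes b_i = S_i / (1 - A) with delta-method gradients
    # ∂b/∂α_j = b/(1-A), ∂b/∂β_ij = 1/(1-A); same pattern for the intercept.
    slopes, lr_se, lr_p, lr_stars = {}, {}, {}, {}
    for r in REGRESSORS:
        dl_names = [f"{r}.L{j}" for j in range(spec.q[r] + 1)]
        S = sum(params[c] for c in dl_names)
        b = S / one_minus_A
        grad = pd.Series(0.0, index=params.index)
        grad[ar_names] = b / one_minus_A
        grad[dl_names] = 1.0 / one_minus_A
        se = _linear_combo_se(cov, grad)
        slopes[r] = float(b)
        lr_se[r] = se
        lr_p[r] = float(2 * stats.t.sf(abs(b / se), df=fit.df_resid)) if se > 0 else float("nan")
        lr_stars[r] = star_labels(lr_p[r]) if not math.isnan(lr_p[r]) else ""
    a0 = params["const"] / one_minus_A
    grad0 = pd.Series(0.0, index=params.index)
    grad0[ar_names] = a0 / one_minus_A
    grad0["const"] = 1.0 / one_minus_A
    a0_se = _linear_combo_se(cov, grad0)
    long_run = LongRunParams(
        outcome=outcome,
        intercept=float(a0),
        intercept_se=a0_se,
        slopes=slopes,
        se=lr_se,
        p_values=lr_p,
        stars=lr_stars,
    )

    # Short-run Δ-terms as exact linear combinations of levels coefficients.
    rows = []

    def add_row(term, variable, lag, weights):
        coef = float(sum(params[c] * wgt for c, wgt in weights.items()))
        se = _linear_combo_se(cov, pd.Series(weights))
        pv = float(2 * stats.t.sf(abs(coef / se), df=fit.df_resid)) if se > 0 else float("nan")
        rows.append(
            {
                "term": term,
                "variable": variable,
                "lag": lag,
                "coef": coef,
                "se": se,
                "p_value": pv,
                "stars": star_labels(pv) if not math.isnan(pv) else "",
            }
        )

    for m in range(1, spec.p):  # λ_m = −Σ_{j>m} α_j
        add_row(f"Δ{outcome}.L{m}", outcome, m,
                {f"{outcome}.L{j}": -1.0 for j in range(m + 1, spec.p + 1)})
    for r in REGRESSORS:
        add_row(f"Δ{r}.L0", r, 0, {f"{r}.L0": 1.0})  # contemporaneous Δx
        for m in range(1, spec.q[r]):  # c_im = −Σ_{j>m} β_ij
            add_row(f"Δ{r}.L{m}", r, m,
                    {f"{r}.L{j}": -1.0 for j in range(m + 1, spec.q[r] + 1)})
    short_run = pd.DataFrame(rows).set_index("term")

    ecm_fit = ECMFit(
        levels=fit,
        theta=float(theta),
        theta_se=theta_se,
        theta_p_value=float(theta_p),
        long_run=long_run,
        short_run=short_run,
        resid=fit.resid.copy(),
    )
    return ecm_fit


def ecm_residuals(ecm: ECMFit) -> pd.Series:
    """Recompute ECM residuals directly from the data via the ECM equation.

    Evaluates Δy_t − [θ v_{t-1} + Σ λ_m Δy_{t-m} + Σ_i (β_{i0} Δx_{i,t} +
    Σ_m c_{im} Δx_{i,t-m})] from the working-scale panel; equals the levels
    residuals up to floating-point error because the re-parameterization is
    exact.  Requires the fit to have been produced through
    :func:`fit_ardl` (so the working frame is attached).
    """
    fit = ecm.levels
    if fit.working is None:
        raise ConfigurationError("fit has no attached working frame; use fit_ardl")
    w, spec, outcome = fit.working, fit.spec, fit.outcome
    idx = fit.response.index
    y = w[outcome]
    dy = y.diff()
    v = y - ecm.long_run.intercept
    for r in REGRESSORS:
        v = v - ecm.long_run.slopes[r] * w[r]
    pred = ecm.theta * v.shift(1)
    sr = ecm.short_run
    for term, row in sr.iterrows():
        var, lag, coef = row["variable"], int(row["lag"]), row["coef"]
        base = dy if var == outcome else w[var].diff()
        pred = pred + coef * base.shift(lag)
    return (dy - pred).loc[idx]
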