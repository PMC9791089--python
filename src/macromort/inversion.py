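"""SDG target inversion: solve the long-run model for required regressor levels.

Given a fitted long-run relation y* = a0 + Σ b_i x_i (working scale) and a
predetermined 2030 mortality target, the inversion answers: *what level must
a single macro instrument reach, holding the others on their no-policy-change
baseline, for the long-run model to deliver the target?*  A log-linear glide
path supplies the intermediate milestone targets (2025, 2027) between the
last observed year and the 2030 horizon, mirroring the constant-proportional
decline that mortality series typically follow.

Because the long-run equation is solved one instrument at a time and there
are two outcome equations (maternal and child), each cell reports the
*binding* requirement — the more demanding of the two solutions, so that
meeting it satisfies both SDG targets.  A dynamic ECM forecast is provided
for verification only: it converges geometrically (rate 1+θ per year) to the
long-run solution and at the horizon differs from it by the residual
unadjusted equilibrium error.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ardl import ECMFit, LongRunParams
from .errors import (
    AlignmentError,
    ConfigurationError,
    NonInvertibleError,
    SizingError,
)
from .panel import DISPLAY_NAMES, LOG_SCALE, MacroPanel, OUTCOMES, REGRESSORS

__all__ = [
    "SDG_TARGETS",
    "TargetSchedule",
    "RegressorPath",
    "InvertedLevel",
    "InversionResult",
    "ForecastResult",
    "glide_path",
    "baseline_paths",
    "invert_single",
    "invert_joint",
    "invert_all",
    "forward_forecast",
]

#: United Nations SDG 3 mortality targets for 2030.
SDG_TARGETS: dict[str, float] = {"maternal": 70.0, "child": 25.0}

#: Slope magnitudes below this cannot be solved for.
INVERT_TOL = 1e-10

#: Working-scale distance from baseline beyond which a requirement is
#: flagged as extreme (reported anyway).
EXTREME_SHIFT = 5.0


@dataclass(frozen=True)
class TargetSchedule:
    """Outcome targets at the horizon year plus intermediate milestones."""

    targets: Mapping[str, float] = field(default_factory=lambda: dict(SDG_TARGETS))
    horizon_year: int = 2030
    milestone_years: tuple[int, ...] = (2025, 2027, 2030)
    glide: str = "log-linear"

    def __post_init__(self):
        for o, v in self.targets.items():
            if o not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome '{o}' in targets")
            if v <= 0:
                raise ConfigurationError(f"target for '{o}' must be > 0, got {v}")
        if sorted(self.milestone_years) != list(self.milestone_years):
            raise ConfigurationError("milestone_years must be ordered")
        if any(m > self.horizon_year for m in self.milestone_years):
            raise ConfigurationError("milestones cannot exceed the horizon year")
        if self.glide not in ("log-linear", "linear"):
            raise ConfigurationError(f"glide must be 'log-linear' or 'linear', got {self.glide!r}")

    def validate_window(self, last_observed_year: int) -> None:
        if self.horizon_year <= last_observed_year:
            raise ConfigurationError(
                f"horizon {self.horizon_year} must lie beyond the last observed "
                f"year {last_observed_year}"
            )
        bad = [m for m in self.milestone_years if m <= last_observed_year]
        if bad:
            raise ConfigurationError(
                f"milestone year(s) {bad} do not lie beyond the last observed year"
            )


@dataclass(frozen=True)
class RegressorPath:
    """Year-indexed regressor values (natural units) with provenance labels.

    Provenance is one of ``observed``, ``baseline-extrapolated`` or
    ``inverted`` per cell.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self):
        years = np.asarray(self.values.index)
        if not np.all(np.diff(years) == 1):
            raise AlignmentError("path years must be contiguous")
        for r in LOG_SCALE:
            if r in self.values.columns and (self.values[r] <= 0).any():
                raise AlignmentError(f"path for '{r}' must stay strictly positive")

    def working(self) -> pd.DataFrame:
        w = self.values.astype(float).copy()
        for c in w.columns:
            if c in LOG_SCALE:
                w[c] = np.log(w[c])
        return w

    def at(self, year: int) -> pd.Series:
        if year not in self.values.index:
            raise AlignmentError(f"year {year} not covered by the regressor path")
        return self.values.loc[year]


def glide_path(last_observed: float, target: float, years, glide: str = "log-linear") -> pd.Series:
    """Outcome trajectory from the last observed value to the horizon target.

    ``years`` runs from the last observed year (where the path equals
    ``last_observed``) to the horizon (where it equals ``target``).  The
    default log-linear glide declines by a constant proportion each year.
    """
    if last_observed <= 0 or target <= 0:
        raise ConfigurationError("glide path endpoints must be strictly positive")
    years = np.asarray(list(years), dtype=int)
    if len(years) < 2 or not np.all(np.diff(years) == 1):
        raise ConfigurationError("glide years must be >= 2 consecutive integers")
    frac = (years - years[0]) / (years[-1] - years[0])
    if glide == "log-linear":
        vals = np.exp(np.log(last_observed) + frac * (np.log(target) - np.log(last_observed)))
    elif glide == "linear":
        vals = last_observed + frac * (target - last_observed)
    else:
        raise ConfigurationError(f"unknown glide '{glide}'")
    return pd.Series(vals, index=pd.Index(years, name="year"))


def baseline_paths(panel: MacroPanel, horizon_year: int) -> RegressorPath:
    """No-policy-change continuation of each regressor to the horizon.

    Fits an OLS linear trend per regressor on the working scale over the
    observed window and extrapolates it; the last observed year anchors the
    path with provenance ``observed``.
    """
    if panel.n_years < 5:
        raise SizingError("need at least 5 observed years to fit baseline trends")
    if horizon_year <= panel.last_year:
        raise ConfigurationError("horizon must lie beyond the observed window")
    w = panel.working()
    obs_years = panel.years.astype(float)
    future_years = np.arange(panel.last_year, horizon_year + 1)
    vals = {}
    for r in REGRESSORS:
        yv = w[r].to_numpy(float)
        slope, intercept = np.polyfit(obs_years, yv, 1)
        proj = intercept + slope * future_years.astype(float)
        proj[0] = yv[-1]  # anchor at the observed endpoint
        vals[r] = np.exp(proj) if r in LOG_SCALE else proj
    values = pd.DataFrame(vals, index=pd.Index(future_years, name="year"))
    prov = pd.DataFrame(
        "baseline-extrapolated", index=values.index, columns=values.columns
    )
    prov.iloc[0] = "observed"
    return RegressorPath(values=values, provenance=prov)


@dataclass(frozen=True)
class InvertedLevel:
    """A single-instrument requirement with its provenance."""

    outcome: str
    variable: str
    year: int
    value: float
    working_value: float
    extreme: bool


def invert_single(
    long_run: LongRunParams,
    target_outcome_value: float,
    year: int,
    variable: str,
    baseline: RegressorPath,
) -> InvertedLevel:
    """Solve the long-run equation for one regressor, others at baseline.

    ``target_outcome_value`` is in natural units (deaths per 100,000 or per
    1,000 live births); the solve happens on the working scale and the
    result is back-transformed.  Requirements far from the baseline are
    reported with an ``extreme`` flag rather than suppressed.
    """
    if variable not in REGRESSORS:
        raise ConfigurationError(f"unknown regressor '{variable}'")
    b = long_run.slopes[variable]
    if abs(b) < INVERT_TOL:
        raise NonInvertibleError(
            f"long-run slope of '{variable}' ({b:.2e}) is too small to invert"
        )
    if target_outcome_value <= 0:
        raise ConfigurationError("outcome target must be strictly positive")
    y_w = (
        np.log(target_outcome_value)
        if long_run.outcome in LOG_SCALE
        else float(target_outcome_value)
    )
    base_w = baseline.working().loc[year]
    rest = sum(long_run.slopes[r] * base_w[r] for r in REGRESSORS if r != variable)
    x_w = (y_w - long_run.intercept - rest) / b
    # extreme requirements may overflow exp; they are reported (as inf)
    # with the magnitude flag rather than suppressed
    with np.errstate(over="ignore"):
        value = float(np.exp(x_w)) if variable in LOG_SCALE else float(x_w)
    extreme = abs(x_w - float(base_w[variable])) > EXTREME_SHIFT
    return InvertedLevel(
        outcome=long_run.outcome,
        variable=variable,
        year=int(year),
        value=value,
        working_value=float(x_w),
        extreme=extreme,
    )


def invert_joint(
    long_run: LongRunParams,
    target_outcome_value: float,
    year: int,
    baseline: RegressorPath,
) -> tuple[dict[str, float], float]:
    """Joint proportional adjustment: move *all* instruments together.

    Each regressor shifts from its baseline working value by s·uᵢ, where
    uᵢ = −sign(bᵢ) is its outcome-improving direction and s ≥ 0 a common
    working-scale step, chosen so the long-run equation hits the target.
    Returns the required natural-unit levels and the step s.  Non-default
    alternative to the single-instrument inversion: each instrument needs
    to move less when all move at once.
    """
    if target_outcome_value <= 0:
        raise ConfigurationError("outcome target must be strictly positive")
    y_w = (
        np.log(target_outcome_value)
        if long_run.outcome in LOG_SCALE
        else float(target_outcome_value)
    )
    base_w = baseline.working().loc[year]
    u = {r: -np.sign(long_run.slopes[r]) for r in REGRESSORS}
    denom = sum(long_run.slopes[r] * u[r] for r in REGRESSORS)
    if abs(denom) < INVERT_TOL:
        raise NonInvertibleError("all long-run slopes are too small to invert jointly")
    s = (y_w - long_run.predict(base_w)) / denom
    levels = {}
    for r in REGRESSORS:
        x_w = float(base_w[r]) + s * u[r]
        levels[r] = float(np.exp(x_w)) if r in LOG_SCALE else float(x_w)
    return levels, float(s)


@dataclass(frozen=True)
class InversionResult:
    """Milestone table of required regressor levels.

    ``table`` has one row per milestone year; the first two columns are the
    glide-path outcome milestones, the remaining five the binding required
    level of each regressor.  ``binding`` records which outcome equation
    produced each requirement, ``extreme_flags`` which cells lie far from
    the baseline.
    """

    table: pd.DataFrame
    binding: pd.DataFrame
    extreme_flags: pd.DataFrame
    glide_paths: dict[str, pd.Series] = field(repr=False)
    schedule: TargetSchedule = field(repr=False, default=None)

    def display(self) -> pd.DataFrame:
        out = self.table.copy()
        out.columns = [DISPLAY_NAMES.get(c, c) for c in out.columns]
        return out


def invert_all(
    fits: Mapping[str, ECMFit],
    schedule: TargetSchedule,
    baseline: RegressorPath,
    last_observed: Mapping[str, float],
    last_observed_year: int,
) -> InversionResult:
    """Per-regressor, per-milestone requirements binding across both outcomes.

    For every regressor whose improvement direction is upward (health, gfc,
    cons, corruption control) the binding requirement is the larger of the
    two per-equation solutions; for unemployment it is the smaller.
    """
    schedule.validate_window(last_observed_year)
    for o in fits:
        if o not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome '{o}'")
    glides = {}
    for o, fit in fits.items():
        years = range(last_observed_year, schedule.horizon_year + 1)
        glides[o] = glide_path(
            float(last_observed[o]), float(schedule.targets[o]), years, schedule.glide
        )
    columns = list(OUTCOMES) + list(REGRESSORS)
    table = pd.DataFrame(
        index=pd.Index(schedule.milestone_years, name="year"), columns=columns, dtype=float
    )
    binding = pd.DataFrame(index=table.index, columns=list(REGRESSORS), dtype=object)
    extreme = pd.DataFrame(False, index=table.index, columns=list(REGRESSORS))
    for year in schedule.milestone_years:
        for o in OUTCOMES:
            if o in glides:
                table.loc[year, o] = glides[o].loc[year]
        any_ok = False
        for r in REGRESSORS:
            candidates: list[InvertedLevel] = []
            for o, fit in fits.items():
                try:
                    candidates.append(
                        invert_single(
                            fit.long_run, float(glides[o].loc[year]), year, r, baseline
                        )
                    )
                except NonInvertibleError:
                    continue
            if not candidates:
                continue
            any_ok = True
            pick = min if r == "unemployment" else max
            chosen = pick(candidates, key=lambda c: c.value)
            table.loc[year, r] = chosen.value
            binding.loc[year, r] = chosen.outcome
            extreme.loc[year, r] = chosen.extreme
        if not any_ok:
            raise NonInvertibleError(
                f"no regressor could be inverted for milestone year {year}"
            )
    return InversionResult(
        table=table,
        binding=binding,
        extreme_flags=extreme,
        glide_paths=glides,
        schedule=schedule,
    )


@dataclass(frozen=True)
class ForecastResult:
    """Dynamic ECM forecast and the pure long-run (steady-state) path."""

    outcome: str
    dynamic: pd.Series
    long_run: pd.Series
    theta: float


def forward_forecast(
    fit: ECMFit, paths: RegressorPath, horizon_year: int
) -> ForecastResult:
    """Dynamic simulation of the fitted ARDL forward with zero future shocks.

    Iterates the levels recursion (equivalent to the ECM, since the two are
    algebraically identical) from the last observed outcome, feeding the
    regressor paths; also returns the steady-state prediction at each year's
    regressor levels.  Both series are back-transformed to natural units.
    """
    levels = fit.levels
    if levels.working is None:
        raise ConfigurationError("fit has no attached working frame; use fit_ardl")
    w = levels.working
    outcome, spec = levels.outcome, levels.spec
    last_year = int(w.index[-1])
    needed = np.arange(last_year, horizon_year + 1)
    missing = [int(y) for y in needed if y not in paths.values.index]
    if missing:
        raise AlignmentError(f"regressor path missing year(s): {missing}")
    pw = paths.working()
    # regressor history: observed years then path years (path overrides at overlap)
    hist = pd.concat([w[list(REGRESSORS)], pw.loc[pw.index > last_year, list(REGRESSORS)]])
    y_hist = dict(zip(w.index.astype(int), w[outcome].astype(float)))
    params = levels.params
    dyn = {}
    lr = {}
    for year in range(last_year + 1, horizon_year + 1):
        val = params["const"]
        for j in range(1, spec.p + 1):
            val += params[f"{outcome}.L{j}"] * y_hist[year - j]
        for r in REGRESSORS:
            for j in range(spec.q[r] + 1):
                val += params[f"{r}.L{j}"] * float(hist[r].loc[year - j])
        y_hist[year] = float(val)
        dyn[year] = float(val)
        lr[year] = fit.long_run.predict(hist.loc[year])
    back = (lambda s: np.exp(s)) if outcome in LOG_SCALE else (lambda s: s)
    dynamic = pd.Series(dyn, name=outcome)
    long_run = pd.Series(lr, name=f"{outcome}_long_run")
    return ForecastResult(
        outcome=outcome, dynamic=back(dynamic), long_run=back(long_run), theta=fit.theta
    )
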