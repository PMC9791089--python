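"""Synthetic annual macro-health panels with known ground truth.

The generator reproduces the statistical structure the ARDL analysis assumes:

* each regressor is a random walk with drift on its working scale, so the
  regressor block is I(1) — the setting the bounds test exists for;
* each mortality outcome is tied to the regressors through an
  error-correction mechanism with a known long-run relation:

      Δy_t = θ · (y_{t-1} − a0 − Σ_i b_i x_{i,t-1}) + ε_t,   θ ∈ (−1, 0)

  on the working scale, which makes outcome and regressors cointegrated by
  construction with cointegrating vector (1, −b) and adjustment speed θ.

Default true parameters are the long-run elasticities and adjustment speeds
of the published Nigeria regressions, so parameter-recovery tests target the
printed values; default scales (start levels, drifts, innovation sizes) are
set to resemble the 1995–2020 Nigerian series in order of magnitude only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import LOG_SCALE, MacroPanel, OUTCOMES, REGRESSORS

__all__ = [
    "LongRunTruth",
    "DGPConfig",
    "simulate_regressors",
    "simulate_outcome",
    "generate_panel",
    "TRUE_LONG_RUN",
    "TRUE_ECT",
]

#: Long-run slopes (working scale) used as the default ground truth.
TRUE_LONG_RUN: dict[str, dict[str, float]] = {
    "maternal": {
        "health": -0.2908,
        "gfc": -0.1211,
        "unemployment": 0.0143,
        "cons": -0.1516,
        "corruption": -0.1097,
    },
    "child": {
        "health": -0.3446,
        "gfc": -0.0123,
        "unemployment": 0.0139,
        "cons": -0.1380,
        "corruption": -0.0713,
    },
}

#: Error-correction adjustment speeds used as the default ground truth.
TRUE_ECT: dict[str, float] = {"maternal": -0.1215, "child": -0.1805}

# Working-scale starting values: health expenditure ≈ 60 bn naira, gross
# fixed capital ≈ 6 bn naira, unemployment 8.5 %, consumption growth 2 %,
# corruption index −1.1 (a mid-1990s-Nigeria order of magnitude).
DEFAULT_START: dict[str, float] = {
    "health": math.log(60.0),
    "gfc": math.log(6.0),
    "unemployment": 8.5,
    "cons": 2.0,
    "corruption": -1.1,
}

# Drifts per year on the working scale: the expenditure aggregates grow a
# few percent a year in real terms; the level-scale series are near-driftless.
DEFAULT_DRIFT: dict[str, float] = {
    "health": 0.085,
    "gfc": 0.055,
    "unemployment": 0.0,
    "cons": 0.0,
    "corruption": -0.01,
}

DEFAULT_INNOVATION_SD: dict[str, float] = {
    "health": 0.08,
    "gfc": 0.10,
    "unemployment": 0.35,
    "cons": 0.80,
    "corruption": 0.12,
}

# Starting outcome levels: maternal ≈ 950 per 100,000 and child ≈ 200 per
# 1,000 live births, matching mid-1990s Nigeria in order of magnitude.
DEFAULT_OUTCOME_START: dict[str, float] = {
    "maternal": math.log(950.0),
    "child": math.log(200.0),
}

#: Annual disturbance of log-mortality around its equilibrium path.
DEFAULT_OUTCOME_NOISE_SD: dict[str, float] = {"maternal": 0.015, "child": 0.015}


@dataclass(frozen=True)
class LongRunTruth:
    """True long-run relation of one outcome: y* = intercept + Σ b_i x_i."""

    intercept: float
    slopes: Mapping[str, float]

    def __post_init__(self):
        missing = [r for r in REGRESSORS if r not in self.slopes]
        if missing:
            raise ConfigurationError(f"long-run slopes missing for: {missing}")

    def steady_state(self, x_working: Mapping[str, float]) -> float:
        return self.intercept + sum(self.slopes[r] * x_working[r] for r in REGRESSORS)


def _default_truth() -> dict[str, LongRunTruth]:
    out = {}
    for outcome in OUTCOMES:
        slopes = TRUE_LONG_RUN[outcome]
        a0 = DEFAULT_OUTCOME_START[outcome] - sum(
            slopes[r] * DEFAULT_START[r] for r in REGRESSORS
        )
        out[outcome] = LongRunTruth(intercept=a0, slopes=dict(slopes))
    return out


@dataclass(frozen=True)
class DGPConfig:
    """Full description of the data-generating process.

    ``drift``, ``innovation_sd`` and ``regressor_start`` are on the working
    scale (log scale for health and gfc, level scale otherwise).
    ``initial_disequilibrium`` places the first outcome observation at the
    stated working-scale distance from its long-run value, which lets tests
    observe the geometric convergence of the equilibrium error directly.
    """

    n_years: int = 26
    start_year: int = 1995
    drift: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    innovation_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INNOVATION_SD)
    )
    regressor_start: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_START)
    )
    true_long_run: Mapping[str, LongRunTruth] = field(default_factory=_default_truth)
    ect_speed: Mapping[str, float] = field(default_factory=lambda: dict(TRUE_ECT))
    outcome_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_NOISE_SD)
    )
    initial_disequilibrium: Mapping[str, float] = field(
        default_factory=lambda: {o: 0.0 for o in OUTCOMES}
    )
    rng_seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_years, (int, np.integer)) or self.n_years < 10:
            raise ConfigurationError(
                f"n_years must be an integer >= 10, got {self.n_years!r}"
            )
        for r in REGRESSORS:
            for m, name in ((self.drift, "drift"), (self.regressor_start, "regressor_start")):
                if r not in m:
                    raise ConfigurationError(f"{name} missing for regressor '{r}'")
            sd = self.innovation_sd.get(r)
            if sd is None or sd < 0:
                raise ConfigurationError(
                    f"innovation_sd for '{r}' must be a nonnegative real, got {sd!r}"
                )
        for o in OUTCOMES:
            theta = self.ect_speed.get(o)
            if theta is None or not (-1.0 < theta < 0.0):
                raise ConfigurationError(
                    f"ect_speed for '{o}' must lie in the open interval (-1, 0), "
                    f"got {theta!r} (explosive or degenerate error correction)"
                )
            sd = self.outcome_noise_sd.get(o)
            if sd is None or sd < 0:
                raise ConfigurationError(
                    f"outcome_noise_sd for '{o}' must be nonnegative, got {sd!r}"
                )
            if o not in self.true_long_run:
                raise ConfigurationError(f"true_long_run missing for outcome '{o}'")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def with_seed(self, seed: int) -> "DGPConfig":
        return replace(self, rng_seed=int(seed))


def _streams(config: DGPConfig) -> dict[str, np.random.Generator]:
    """Independent, reproducible RNG streams for each simulator stage."""
    children = np.random.SeedSequence(config.rng_seed).spawn(1 + len(OUTCOMES))
    streams = {"regressors": np.random.default_rng(children[0])}
    for i, o in enumerate(OUTCOMES):
        streams[o] = np.random.default_rng(children[1 + i])
    return streams


def simulate_regressors(
    config: DGPConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the regressor block as random walks with drift.

    Returns a year-indexed DataFrame on the working scale.  With all
    innovation standard deviations zero each series is an exact (log-)linear
    trend.
    """
    if rng is None:
        rng = _streams(config)["regressors"]
    T = config.n_years
    out = {}
    for r in REGRESSORS:
        shocks = rng.normal(0.0, config.innovation_sd[r], size=T - 1)
        steps = config.drift[r] + shocks
        out[r] = config.regressor_start[r] + np.concatenate(([0.0], np.cumsum(steps)))
    return pd.DataFrame(out, index=pd.Index(config.years, name="year"))


def simulate_outcome(
    config: DGPConfig,
    regressors: pd.DataFrame,
    outcome: str,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Simulate one outcome (working scale) from the error-correction law.

    The first observation sits at the long-run value implied by the first
    regressor row plus the configured initial disequilibrium; thereafter
    Δy_t = θ·(y_{t-1} − a0 − Σ b_i x_{i,t-1}) + ε_t.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome '{outcome}'")
    if rng is None:
        rng = _streams(config)[outcome]
    theta = config.ect_speed[outcome]
    truth = config.true_long_run[outcome]
    sd = config.outcome_noise_sd[outcome]
    X = regressors[list(REGRESSORS)].to_numpy(float)
    b = np.array([truth.slopes[r] for r in REGRESSORS])
    equilibrium = truth.intercept + X @ b
    T = len(regressors)
    eps = rng.normal(0.0, sd, size=T)
    y = np.empty(T)
    y[0] = equilibrium[0] + config.initial_disequilibrium[outcome] + eps[0]
    for t in range(1, T):
        v_prev = y[t - 1] - equilibrium[t - 1]
        y[t] = y[t - 1] + theta * v_prev + eps[t]
    return pd.Series(y, index=regressors.index, name=outcome)


def generate_panel(config: DGPConfig) -> MacroPanel:
    """Simulate a complete panel (both outcomes, all regressors).

    Pure function of the configuration: the same seed yields a bit-identical
    panel, and regressor and outcome streams are independent, so
    ``generate_panel`` equals the composition of the two simulators.
    """
    streams = _streams(config)
    regs = simulate_regressors(config, rng=streams["regressors"])
    working = regs.copy()
    for o in OUTCOMES:
        working[o] = simulate_outcome(config, regs, o, rng=streams[o])
    return MacroPanel.from_working(working)
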