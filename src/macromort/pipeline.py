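"""End-to-end pipeline: simulate/read → fit → test → invert → report.

Each run produces, in the output directory:

* ``report.json`` — every statistic in machine-readable form (byte-identical
  across runs with the same configuration and seed);
* ``report.txt``  — the human-readable regression and forecast tables, in
  the conventional layout (short-run block, ECT row, long-run block,
  diagnostics, then the milestone forecast table);
* ``panel.csv``   — the simulated panel (simulate mode only);
* ``run.log``     — seed, package versions and settings.

Every number printed in ``report.txt`` is present in ``report.json``.
"""
from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ardl import ECMFit, fit_ardl, select_lags, star_labels, to_ecm
from .diagnostics import (
    bounds_f_test,
    correlation_screen,
    heteroscedasticity_test,
    serial_correlation_test,
    unit_root_test,
)
from .errors import MacromortError, PipelineStageError
from .inversion import InversionResult, baseline_paths, forward_forecast, invert_all
from .io import PipelineConfig, read_panel, write_panel
from .panel import COLUMNS, DISPLAY_NAMES, MacroPanel, REGRESSORS
from .simulate import generate_panel

__all__ = ["ReportBundle", "run_pipeline"]


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    panel: MacroPanel
    fits: dict[str, ECMFit]
    report: dict = field(repr=False)
    inversion: InversionResult | None = None
    output_dir: Path | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except MacromortError as e:
                raise PipelineStageError(name, e) from e
        return wrapped
    return deco


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _round(x, nd=10):
    v = _jsonable(x)
    return round(v, nd) if isinstance(v, float) else v


def _fit_block(ecm: ECMFit) -> dict:
    lr = ecm.long_run
    block = {
        "spec": {"p": ecm.spec.p, "q": dict(ecm.spec.q), "trend": ecm.spec.trend},
        "nobs": ecm.levels.nobs,
        "aic": _round(ecm.levels.aic),
        "sic": _round(ecm.levels.sic),
        "sigma2": _round(ecm.levels.sigma2),
        "ect": {
            "coef": _round(ecm.theta),
            "se": _round(ecm.theta_se),
            "p_value": _round(ecm.theta_p_value),
            "stars": star_labels(ecm.theta_p_value),
        },
        "short_run": {
            term: {
                "coef": _round(row["coef"]),
                "se": _round(row["se"]),
                "p_value": _round(row["p_value"]),
                "stars": row["stars"],
            }
            for term, row in ecm.short_run.iterrows()
        },
        "long_run": {
            "intercept": {"coef": _round(lr.intercept), "se": _round(lr.intercept_se)},
            **{
                r: {
                    "coef": _round(lr.slopes[r]),
                    "se": _round(lr.se[r]),
                    "p_value": _round(lr.p_values[r]),
                    "stars": lr.stars[r],
                }
                for r in REGRESSORS
            },
        },
        "diagnostics": {
            name: {
                "statistic": _round(d.statistic),
                "p_value": _round(d.p_value),
                "rendered": str(d),
            }
            for name, d in ecm.diagnostics.items()
            if hasattr(d, "statistic")
        },
    }
    if "bounds" in ecm.diagnostics:
        b = ecm.diagnostics["bounds"]
        block["diagnostics"]["bounds"] = {
            "f_stat": _round(b.f_stat),
            "k": b.k,
            "case": b.case,
            "bounds": {f"{lvl:.2f}": list(bnd) for lvl, bnd in sorted(b.bounds.items())},
            "decisions": {f"{lvl:.2f}": d for lvl, d in sorted(b.decisions.items())},
            "rendered": str(b),
        }
    return block


def _render_table1(fits: dict[str, ECMFit]) -> list[str]:
    outcomes = list(fits)
    header = ["ARDL"] + [f"{DISPLAY_NAMES[o]} mortality" for o in outcomes]
    rows: list[list[str]] = [header]

    def cell(coef, se, stars):
        return f"{coef:.4f}{stars} ({se:.4f})"

    rows.append(
        ["ECT(-1)"]
        + [cell(f.theta, f.theta_se, star_labels(f.theta_p_value)) for f in fits.values()]
    )
    for r in REGRESSORS:
        term = f"Δ{r}.L0"
        line = [f"Δ{DISPLAY_NAMES[r]}"]
        for f in fits.values():
            if term in f.short_run.index:
                row = f.short_run.loc[term]
                line.append(cell(row["coef"], row["se"], row["stars"]))
            else:
                line.append("-")
        rows.append(line)
    for r in REGRESSORS:
        rows.append(
            [DISPLAY_NAMES[r]]
            + [
                cell(f.long_run.slopes[r], f.long_run.se[r], f.long_run.stars[r])
                for f in fits.values()
            ]
        )
    for label, key in (
        ("F (Bounds test)", "bounds"),
        ("Serial correlation", "serial_correlation"),
        ("Heteroscedasticity", "heteroscedasticity"),
    ):
        line = [label]
        for f in fits.values():
            d = f.diagnostics.get(key)
            line.append(str(d) if d is not None else "-")
        rows.append(line)
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return ["  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows]


def _render_inversion(inv: InversionResult) -> list[str]:
    df = inv.display()
    lines = ["Milestone forecasts (required levels, binding across outcome equations):"]
    header = ["Forecasts"] + list(df.columns)
    rows = [header]
    for year, row in df.iterrows():
        rows.append([str(year)] + [f"{v:,.2f}" if pd.notna(v) else "-" for v in row])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines += ["  ".join(c.rjust(w) for c, w in zip(r, widths)) for r in rows]
    return lines


@_stage("load")
def _load_panel(config: PipelineConfig) -> MacroPanel:
    if config.dgp is not None:
        return generate_panel(config.dgp)
    return read_panel(config.input_path)


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Run every stage and (optionally) write the report bundle to disk."""
    panel = _load_panel(config)

    @_stage("lag-selection")
    def _select(outcome):
        if config.spec is not None:
            return config.spec
        return select_lags(panel, outcome, config.p_max, config.q_max, config.criterion)

    @_stage("estimation")
    def _fit(outcome, spec):
        return to_ecm(fit_ardl(panel, spec, outcome))

    @_stage("inference")
    def _tests(ecm):
        levels = ecm.levels
        ecm.diagnostics["bounds"] = bounds_f_test(panel, levels.spec, levels.outcome)
        ecm.diagnostics["serial_correlation"] = serial_correlation_test(
            levels.resid, levels.design, config.serial_lags
        )
        ecm.diagnostics["heteroscedasticity"] = heteroscedasticity_test(
            levels.resid, levels.design
        )

    fits: dict[str, ECMFit] = {}
    for outcome in config.outcomes:
        spec = _select(outcome)
        ecm = _fit(outcome, spec)
        _tests(ecm)
        fits[outcome] = ecm

    report: dict = {
        "package": {"name": "macromort", "version": __version__},
        "seed": config.rng_seed,
        "settings": {
            "mode": "simulate" if config.dgp is not None else "fit",
            "outcome": config.outcome,
            "criterion": config.criterion,
            "p_max": config.p_max,
            "q_max": config.q_max,
            "serial_lags": config.serial_lags,
            "fast": config.fast,
            "horizon_year": config.schedule.horizon_year,
            "milestone_years": list(config.schedule.milestone_years),
            "targets": {k: v for k, v in sorted(config.schedule.targets.items())},
        },
        "panel": {
            "first_year": int(panel.years[0]),
            "last_year": panel.last_year,
            "n_years": panel.n_years,
        },
        "fits": {o: _fit_block(f) for o, f in fits.items()},
    }

    if not config.fast:
        @_stage("integration-screen")
        def _screens():
            w = panel.working()
            unit_roots = {}
            for col in COLUMNS:
                res = unit_root_test(w[col], max_lag=config.unit_root_max_lag)
                unit_roots[col] = {
                    "statistic": _round(res.statistic),
                    "p_value": _round(res.p_value),
                    "diff_statistic": _round(res.diff_statistic),
                    "diff_p_value": _round(res.diff_p_value),
                    "lag_order": res.lag_order,
                    "integration_order": res.integration_order,
                }
            screen = correlation_screen(panel)
            return unit_roots, screen

        unit_roots, screen = _screens()
        report["unit_roots"] = unit_roots
        report["correlation_screen"] = {
            "matrix": {
                a: {b: _round(float(screen.matrix.loc[a, b])) for b in screen.matrix.columns}
                for a in screen.matrix.index
            },
            "collinear_pairs": [[a, b, _round(r)] for a, b, r in screen.flags],
            "threshold": screen.threshold,
        }

    @_stage("inversion")
    def _invert():
        baseline = baseline_paths(panel, config.schedule.horizon_year)
        last_obs = {o: float(panel.data[o].iloc[-1]) for o in config.outcomes}
        inv = invert_all(fits, config.schedule, baseline, last_obs, panel.last_year)
        forecasts = {
            o: forward_forecast(f, baseline, config.schedule.horizon_year)
            for o, f in fits.items()
        }
        return inv, forecasts, baseline

    inv, forecasts, baseline = _invert()
    report["inversion"] = {
        "milestones": {
            str(year): {c: _round(v) if pd.notna(v) else None for c, v in row.items()}
            for year, row in inv.table.iterrows()
        },
        "binding_equation": {
            str(year): {c: (v if isinstance(v, str) else None) for c, v in row.items()}
            for year, row in inv.binding.iterrows()
        },
        "extreme_flags": {
            str(year): {c: bool(v) for c, v in row.items()}
            for year, row in inv.extreme_flags.iterrows()
        },
    }
    report["forecast_verification"] = {
        o: {
            "dynamic_at_horizon": _round(float(fc.dynamic.iloc[-1])),
            "long_run_at_horizon": _round(float(fc.long_run.iloc[-1])),
            "theta": _round(fc.theta),
        }
        for o, fc in forecasts.items()
    }

    bundle = ReportBundle(
        config=config, panel=panel, fits=fits, report=report, inversion=inv
    )

    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
        lines = _render_table1(fits) + [""] + _render_inversion(inv)
        (outdir / "report.txt").write_text("\n".join(lines) + "\n")
        if config.dgp is not None:
            write_panel(panel, outdir / "panel.csv")
        log = [
            f"macromort {__version__}",
            f"python {sys.version.split()[0]}",
            f"numpy {np.__version__}, pandas {pd.__version__}",
            f"seed = {config.rng_seed}",
            f"settings = {json.dumps(report['settings'], sort_keys=True)}",
        ]
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        bundle.output_dir = outdir
    return bundle
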