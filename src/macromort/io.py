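"""Panel file ingestion and pipeline configuration.

The on-disk format is a tidy one-row-per-year CSV with header

    year,maternal,child,health,gfc,unemployment,cons,corruption

in natural units.  Reading validates the schema cell by cell and reports
row/column positions for anything unparseable; year gaps, duplicate years
and nonpositive values in the log-scale columns are rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ardl import ARDLSpec
from .errors import ConfigurationError, PanelValidationError
from .inversion import TargetSchedule
from .panel import COLUMNS, MacroPanel
from .simulate import DGPConfig

__all__ = ["read_panel", "write_panel", "PipelineConfig", "parse_config_file"]

CSV_HEADER = ("year",) + COLUMNS


def read_panel(path: str | Path) -> MacroPanel:
    """Read and validate a tidy annual panel CSV."""
    path = Path(path)
    if not path.exists():
        raise PanelValidationError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in CSV_HEADER if c not in raw.columns]
    if missing:
        raise PanelValidationError(f"{path.name}: missing column(s) {missing}")
    parsed = {}
    for col in CSV_HEADER:
        s = raw[col].str.replace(",", "", regex=False).str.strip()
        vals = pd.to_numeric(s, errors="coerce")
        bad = raw.index[vals.isna() & s.notna() & (s != "")]
        if len(bad):
            i = int(bad[0])
            raise PanelValidationError(
                f"{path.name}: unparseable cell at row {i + 2}, column '{col}': "
                f"{raw.loc[i, col]!r}"
            )
        nan_rows = raw.index[vals.isna()]
        if len(nan_rows):
            raise PanelValidationError(
                f"{path.name}: empty cell at row {int(nan_rows[0]) + 2}, column '{col}'"
            )
        parsed[col] = vals
    years = parsed["year"]
    if not np.allclose(years, years.round()):
        raise PanelValidationError(f"{path.name}: non-integer year values")
    df = pd.DataFrame({c: parsed[c] for c in COLUMNS})
    df.index = pd.Index(years.astype(int), name="year")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise PanelValidationError(f"{path.name}: duplicate year(s) {sorted(set(dup))}")
    return MacroPanel(df)


def write_panel(panel: MacroPanel, path: str | Path) -> Path:
    """Write a panel to the documented tidy CSV dialect."""
    path = Path(path)
    out = panel.data[list(COLUMNS)].copy()
    out.insert(0, "year", panel.years)
    out.to_csv(path, index=False, float_format="%.10g")
    return path


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs; exactly one data source.

    Either ``input_path`` (fit mode, reads the tidy CSV) or ``dgp``
    (simulate mode) must be given, never both.
    """

    input_path: str | None = None
    dgp: DGPConfig | None = None
    outcome: str = "both"
    spec: ARDLSpec | None = None
    p_max: int = 2
    q_max: int = 2
    criterion: str = "aic"
    serial_lags: int = 2
    unit_root_max_lag: int = 4
    schedule: TargetSchedule = field(default_factory=TargetSchedule)
    output_dir: str = "macromort_out"
    rng_seed: int = 0
    fast: bool = False

    def __post_init__(self):
        if (self.input_path is None) == (self.dgp is None):
            raise ConfigurationError(
                "exactly one of input_path (fit mode) or dgp (simulate mode) "
                "must be provided"
            )
        if self.outcome not in ("maternal", "child", "both"):
            raise ConfigurationError(f"outcome must be maternal|child|both, got {self.outcome!r}")
        if self.criterion not in ("aic", "sic"):
            raise ConfigurationError(f"criterion must be aic|sic, got {self.criterion!r}")

    @property
    def outcomes(self) -> tuple[str, ...]:
        return ("maternal", "child") if self.outcome == "both" else (self.outcome,)


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key = value`` configuration file (# comments allowed)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, val = stripped.split("=", 1)
        out[key.strip()] = val.strip()
    return out
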