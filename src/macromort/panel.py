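"""Annual macro-health panel container.

The analysis operates on a tidy annual table: two mortality outcomes and five
macro-economic regressors for a single country.  Mortality rates and the two
expenditure aggregates are strictly positive and are modelled on the natural
log scale ("working scale"); unemployment, household-consumption growth and
the control-of-corruption index stay in levels (corruption is an index that
is routinely negative, so it cannot be logged).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PanelValidationError

OUTCOMES: tuple[str, ...] = ("maternal", "child")
REGRESSORS: tuple[str, ...] = ("health", "gfc", "unemployment", "cons", "corruption")
COLUMNS: tuple[str, ...] = OUTCOMES + REGRESSORS
#: Columns modelled in natural logs; all are strictly positive by definition
#: (deaths per live birth, billions of naira).
LOG_SCALE: tuple[str, ...] = ("maternal", "child", "health", "gfc")

#: Human-readable names used in reports (mirrors the regression tables).
DISPLAY_NAMES = {
    "maternal": "Maternal",
    "child": "Child",
    "health": "Health expenditure",
    "gfc": "GFC",
    "unemployment": "Unemployment",
    "cons": "Consumption",
    "corruption": "Cont. corruption",
}

MIN_YEARS = 10


@dataclass(frozen=True)
class MacroPanel:
    """Validated year-indexed panel in natural units.

    Parameters
    ----------
    data
        DataFrame indexed by calendar year with columns
        ``maternal, child, health, gfc, unemployment, cons, corruption``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"missing columns: {missing}")
        years = np.asarray(df.index)
        if len(years) < MIN_YEARS:
            raise PanelValidationError(
                f"panel has {len(years)} years; at least {MIN_YEARS} required"
            )
        if not np.issubdtype(years.dtype, np.integer):
            raise PanelValidationError("year index must be integer calendar years")
        dup = pd.Index(years)[pd.Index(years).duplicated()]
        if len(dup):
            raise PanelValidationError(f"duplicate year(s): {sorted(set(dup))}")
        if not np.all(np.diff(years) == 1):
            gaps = [int(years[i]) for i in range(len(years) - 1) if years[i + 1] - years[i] != 1]
            raise PanelValidationError(f"years must be consecutive; gap(s) after {gaps}")
        block = df[list(COLUMNS)]
        if block.isna().any().any():
            bad = [
                (int(y), c)
                for c in COLUMNS
                for y in df.index[df[c].isna()]
            ]
            raise PanelValidationError(f"missing values at (year, column): {bad[:10]}")
        for c in LOG_SCALE:
            nonpos = df.index[df[c] <= 0]
            if len(nonpos):
                raise PanelValidationError(
                    f"column '{c}' must be strictly positive (log scale); "
                    f"offending year(s): {[int(y) for y in nonpos[:10]]}"
                )

    # ------------------------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.data.index)

    @property
    def n_years(self) -> int:
        return len(self.data)

    @property
    def last_year(self) -> int:
        return int(self.data.index[-1])

    def working(self) -> pd.DataFrame:
        """Panel on the working scale: logs for positive-constrained columns."""
        w = self.data[list(COLUMNS)].astype(float).copy()
        for c in LOG_SCALE:
            w[c] = np.log(w[c])
        return w

    @classmethod
    def from_working(cls, working: pd.DataFrame) -> "MacroPanel":
        """Inverse of :meth:`working` (exponentiates the log-scale columns)."""
        df = working[list(COLUMNS)].astype(float).copy()
        for c in LOG_SCALE:
            df[c] = np.exp(df[c])
        return cls(df)

    def regressors_working(self) -> pd.DataFrame:
        return self.working()[list(REGRESSORS)]
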