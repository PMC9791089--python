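import numpy as np
import pandas as pd
import pytest

import macromort as mm
from macromort.panel import COLUMNS, REGRESSORS


@pytest.fixture(scope="session")
def default_config() -> mm.DGPConfig:
    return mm.DGPConfig(rng_seed=42)


@pytest.fixture(scope="session")
def default_panel(default_config) -> mm.MacroPanel:
    return mm.generate_panel(default_config)


@pytest.fixture(scope="session")
def long_panel() -> mm.MacroPanel:
    """A T = 2,000 panel for asymptotic checks."""
    return mm.generate_panel(mm.DGPConfig(n_years=2000, rng_seed=1))


@pytest.fixture()
def toy_working() -> pd.DataFrame:
    """A 10-row deterministic working-scale frame for exact oracles."""
    T = 10
    t = np.arange(T, dtype=float)
    data = {
        "maternal": 5.0 - 0.05 * t + 0.01 * (t % 3),
        "child": 4.0 - 0.03 * t,
        "health": 3.0 + 0.10 * t + 0.02 * (t % 2),
        "gfc": 2.0 + 0.05 * t,
        "unemployment": 8.0 + 0.2 * np.sin(t),
        "cons": 1.0 + 0.3 * np.cos(t),
        "corruption": -1.0 + 0.05 * t,
    }
    return pd.DataFrame(data, index=pd.RangeIndex(T, name="year") + 2000)


def noiseless_config(**overrides) -> mm.DGPConfig:
    base = dict(
        innovation_sd={r: 0.0 for r in REGRESSORS},
        outcome_noise_sd={"maternal": 0.0, "child": 0.0},
    )
    base.update(overrides)
    return mm.DGPConfig(**base)
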