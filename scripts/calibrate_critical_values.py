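"""Regenerate the embedded Monte-Carlo critical values.

Simulates the null distributions behind ``macromort._critical_values``:

* bounds-test F statistic for k = 5 level regressors (intercept, no trend),
  with every regressor I(1) (upper bound) and every regressor I(0) (lower
  bound), at T = 1,000 with 20,000 replicates;
* Dickey-Fuller t-statistic for the constant-only and constant-plus-trend
  regressions at T = 1,000 with 100,000 replicates.

Run from the repository root:  python scripts/calibrate_critical_values.py
Paste the printed dictionaries into ``src/macromort/_critical_values.py``.
"""
from __future__ import annotations

import numpy as np

T = 1000
K = 5
BOUNDS_REPS = 20_000
DF_REPS = 100_000
LEVELS = (0.10, 0.05, 0.01)
DF_PROBS = [0.001, 0.01, 0.025, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99, 0.999]


def bounds_f(rng: np.random.Generator, stationary_x: bool) -> float:
    y = np.cumsum(rng.standard_normal(T))
    shocks = rng.standard_normal((T, K))
    x = shocks if stationary_x else np.cumsum(shocks, axis=0)
    dy = np.diff(y)
    dx = np.diff(x, axis=0)
    # rows t = 1..T-1: dy_t on const, y_{t-1}, x_{t-1}, dx_t
    Xu = np.column_stack([np.ones(T - 1), y[:-1], x[:-1], dx])
    Xr = np.column_stack([np.ones(T - 1), dx])
    _, ssr_u, _, _ = np.linalg.lstsq(Xu, dy, rcond=None)
    _, ssr_r, _, _ = np.linalg.lstsq(Xr, dy, rcond=None)
    ssr_u, ssr_r = float(ssr_u[0]), float(ssr_r[0])
    n, ku = Xu.shape
    return ((ssr_r - ssr_u) / (K + 1)) / (ssr_u / (n - ku))


def df_tau(rng: np.random.Generator, trend: bool) -> float:
    y = np.cumsum(rng.standard_normal(T))
    dy = np.diff(y)
    cols = [np.ones(T - 1), y[:-1]]
    if trend:
        cols.append(np.arange(T - 1, dtype=float))
    X = np.column_stack(cols)
    beta, ssr, _, _ = np.linalg.lstsq(X, dy, rcond=None)
    sigma2 = float(ssr[0]) / (X.shape[0] - X.shape[1])
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    return float(beta[1] / se)


def main() -> None:
    rng = np.random.default_rng(20240801)
    upper = np.array([bounds_f(rng, stationary_x=False) for _ in range(BOUNDS_REPS)])
    lower = np.array([bounds_f(rng, stationary_x=True) for _ in range(BOUNDS_REPS)])
    print("BOUNDS_K5 = {")
    for lvl in LEVELS:
        lo = np.quantile(lower, 1 - lvl)
        hi = np.quantile(upper, 1 - lvl)
        print(f"    {lvl}: ({lo:.3f}, {hi:.3f}),")
    print("}")

    for trend, label in ((False, "c"), (True, "ct")):
        taus = np.array([df_tau(rng, trend) for _ in range(DF_REPS)])
        qs = np.quantile(taus, DF_PROBS)
        print(f'DF_QUANTILES["{label}"] = [' + ", ".join(f"{q:.4f}" for q in qs) + "]")


if __name__ == "__main__":
    main()
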