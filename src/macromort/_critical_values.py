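"""Embedded critical values.

All constants in this module were produced by the package's own Monte Carlo
calibration (``scripts/calibrate_critical_values.py``); rerun that script to
regenerate them.

* ``BOUNDS_K5``: lower/upper critical bounds of the cointegration F-test for
  k = 5 level regressors, intercept and no trend, simulated at T = 1,000
  with 20,000 replicates.  The lower bound is the null quantile when every
  regressor is I(0), the upper bound when every regressor is I(1).
* ``DF_QUANTILES``: null quantiles of the Dickey-Fuller t-statistic
  (constant-only and constant-plus-trend regressions), simulated at
  T = 1,000 with 100,000 replicates; used both for 1/5/10% verdicts and for
  interpolated approximate p-values.
"""

BOUNDS_K5: dict[float, tuple[float, float]] = {
    0.10: (2.250, 3.357),
    0.05: (2.605, 3.817),
    0.01: (3.350, 4.764),
}

DF_PROBS: list[float] = [0.001, 0.01, 0.025, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99, 0.999]

DF_QUANTILES: dict[str, list[float]] = {
    "c": [-4.1041, -3.4389, -3.1325, -2.8651, -2.5691, -2.0878, -1.5632,
          -1.0128, -0.4362, -0.0741, 0.6320, 1.4474],
    "ct": [-4.6369, -3.9736, -3.6758, -3.4224, -3.1319, -2.6715, -2.1802,
           -1.7026, -1.2380, -0.9287, -0.3340, 0.4157],
}
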