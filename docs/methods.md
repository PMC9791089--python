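# Methods

## The model

`macromort` analyses an annual country-level panel of two mortality outcomes
— maternal deaths per 100,000 live births and under-five deaths per 1,000
live births — against five macro-economic regressors: total health
expenditure (billion naira), gross fixed capital (billion naira),
unemployment (%), household-consumption growth (%), and a
control-of-corruption index. Macro aggregates of this kind are typically
integrated of order one, and samples are short (a few decades of annual
data), which is the setting the ARDL bounds approach to cointegration was
designed for: the levels regression is estimable by OLS whether individual
series are I(0) or I(1), and the existence of a long-run relation is judged
against a pair of critical bounds rather than a single critical value.

### Working scale

Mortality rates and the two expenditure aggregates are strictly positive
and are modelled in natural logs, so their long-run coefficients are
elasticities. Unemployment, consumption growth and the corruption index
stay in levels; the corruption index is routinely negative and cannot be
logged. Throughout the package "working scale" means exactly this mapping.
A consequence: unemployment is not sign-constrained on the working scale.
Real unemployment rates are positive, but a level-scale random walk cannot
be, so positivity is validated (at panel construction and CSV read) only
for the four log-scale columns.

### Estimation route

For each outcome the package fits the levels ARDL(p, q₁..q₅)

    y_t = β₀ + Σⱼ αⱼ y_{t−j} + Σᵢ Σⱼ β_{ij} x_{i,t−j} + ε_t

by OLS and then re-parameterizes *algebraically* to the error-correction
form

    Δy_t = θ v_{t−1} + Σ λ_m Δy_{t−m} + Σᵢ (β_{i0} Δx_{i,t} + Σ_m c_{im} Δx_{i,t−m}) + ε_t

with θ = −(1 − Σαⱼ), long-run slopes bᵢ = Σⱼβ_{ij}/(1 − Σαⱼ), and
v_{t−1} = y_{t−1} − a₀ − Σᵢ bᵢ x_{i,t−1}. Because this is an exact
re-parameterization (not a second regression), ECM and levels fitted values
and residuals are identical; the test suite asserts this to 10⁻⁸. The
alternative one-step conditional-ECM regression would give the same point
estimates and is not implemented. Long-run standard errors come from the
delta method applied to the OLS coefficient covariance; short-run Δ-term
standard errors are exact linear-combination variances. Inference uses the
classical (homoscedastic) covariance s²(XᵀX)⁻¹ — no robust option is
currently wired in.

Lag orders are chosen by exhaustive grid search over
(p, q₁..q₅) ∈ [1..p_max]×[0..q_max]⁵ on a common effective sample, AIC by
default with p_max = q_max = 2: an annual sample of ~26 observations cannot
support deeper lags with five regressors. Ties break toward fewer
parameters, then lexicographically. A sum of squares at numerical zero
(exact interpolation) is treated as a perfect fit so that noiseless data
select the smallest exact model rather than one favoured by rounding noise.
Deterministic-trend support ("ct") exists in the levels fit, lag selection,
bounds test and unit-root test, but the ECM extraction and the target
inversion require intercept-only fits: the outcome equations carry no trend
term, and a trend would make the long-run inversion year-dependent.
`to_ecm` raises when |1 − Σα| < 10⁻⁸ (no identified long-run relation).

### Inference

* **Bounds F-test.** Δy is regressed on an intercept, the lagged levels of
  the outcome and all five regressors, and the short-run differences the
  ARDL specification implies; the F statistic tests joint nullity of the
  six level terms. Critical bounds for k = 5, intercept/no-trend, are
  embedded constants produced by the package's own Monte Carlo
  (`scripts/calibrate_critical_values.py`: T = 1,000, 20,000 replicates;
  lower bound from all-I(0) regressors, upper from all-I(1)). The simulated
  5% bounds (2.605/3.817) agree with the standard asymptotic tabulations to
  two decimals.
* **Serial correlation.** Breusch-Godfrey LM test in F form: residuals on
  the original regressors plus lagged residuals (default 2 lags, pre-sample
  lags zero).
* **Heteroscedasticity.** Breusch-Pagan in F form: squared residuals on the
  levels of the original regressors.
* **Unit roots.** Augmented Dickey-Fuller regression; lag order by SIC up
  to 4 on a common sample, statistic refitted at the chosen lag on the full
  available sample. Verdicts use 1/5/10% quantiles from the same embedded
  Monte Carlo; p-values are piecewise-linear interpolations over a 12-point
  quantile grid, so they are approximate (good to a few hundredths in the
  central region) and clipped to [10⁻⁴, 1−10⁻⁴]. The reported
  integration-order label (I(0)/I(1)/I(2)+) combines the level and
  first-difference verdicts at 5%.
  The exact test variants behind published "statistic [p]" rows are rarely
  named; these defaults are the package's choice, configurable, and not
  asserted to match any particular software.
* **Collinearity screen.** Pairwise Pearson correlations among the
  regressors on the working scale; |r| > 0.9 is flagged.

### Target inversion

The 2030 SDG targets (maternal 70 per 100,000, under-five 25 per 1,000)
enter as predetermined future outcome values. A log-linear glide path —
constant proportional decline, the shape mortality trajectories typically
follow — connects the last observed value to the horizon target and
supplies intermediate milestone values (2025, 2027 by default). Published
milestone tables print values slightly below the official targets (69.5 at
2030, for example); the schedule treats whatever target it is given as
exact, so reproducing such a table means supplying its printed milestone as
the target.

The long-run equation is one equation in five unknowns, so the inversion is
single-instrument by construction: each cell of the milestone table answers
"what must this regressor alone be, the others held on their no-policy-change
baseline, for the long-run equation to deliver the milestone?" The baseline
is an OLS linear trend per regressor on the working scale, anchored at the
last observed value. With two outcome equations, each cell reports the
*binding* requirement — the larger of the two solutions for instruments
whose improvement direction is upward (health, gfc, consumption, corruption
control), the smaller for unemployment — so that meeting the reported level
satisfies both targets; the binding equation is recorded per cell.

A joint proportional-adjustment mode (`invert_joint`) is provided as a
non-default alternative: all five instruments move together from baseline
by a common working-scale step along their outcome-improving directions,
so each moves less than its single-instrument requirement. The milestone
table uses the single-instrument mode because its one-value-per-regressor
layout matches how such forecasts are conventionally reported.

Inversion always uses the long-run (steady-state) equation. The dynamic ECM
forecast (the fitted levels recursion iterated forward with zero shocks) is
exposed for verification: it converges to the long-run solution
geometrically at rate 1 + θ per year, and at the horizon differs from it by
the residual unadjusted equilibrium error — small but nonzero, which is why
it is not used for the inversion itself. Requirements whose working-scale
distance from baseline exceeds 5 (roughly a 150-fold change for a logged
variable) are flagged as extreme but still reported; log-scale requirements
are positive by construction.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular country's history. Regressors are independent random walks
with drift on the working scale; each outcome follows the error-correction
law Δy_t = θ(y_{t−1} − a₀ − Σ bᵢ x_{i,t−1}) + ε_t, making outcome and
regressors cointegrated by construction with known long-run coefficients
and adjustment speed. Defaults:

| parameter | default | why |
|---|---|---|
| window | 1995–2020 (T = 26) | the published study window |
| long-run slopes, θ | the published maternal/child estimates (health −0.2908/−0.3446, ECT −0.1215/−0.1805, …) | recovery tests then target printed values |
| regressor starts | health 60 bn, gfc 6 bn, unemployment 8.5%, cons 2%, corruption −1.1 | mid-1990s Nigeria orders of magnitude |
| drifts | log-health +0.085/yr, log-gfc +0.055/yr, others ≈ 0 | reproduces the observed growth of the aggregates over 26 years |
| innovation sd | 0.08–0.12 (log scales), 0.35–0.8 (level scales) | annual macro volatility of the right size |
| outcome noise sd | 0.015 (log scale) | mortality series are smooth year to year |

Outcome intercepts a₀ are derived so the 1995 steady state sits at maternal
≈ 950 and child ≈ 200. An `initial_disequilibrium` knob displaces the first
observation from the long-run value so tests can watch the equilibrium
error contract by exactly (1+θ) per period on noiseless input.

What the generator does **not** emulate: actual WDI values, structural
breaks, measurement revisions, missing data, or cross-regressor
correlation. Passing recovery tests therefore show that the estimator
recovers the truth *under the model's own assumptions*, not that the
published coefficients are correct for Nigeria.

Realism (T = 26) and statistical verification are deliberately separated:
at 26 observations estimates of a θ of −0.12 are extremely noisy, so
recovery tests run at T = 2,000 with 200 replicates, where the means of the
long-run estimates land within a few thousandths of the truth.

One specification subtlety, documented rather than hidden: the DGP dates
the equilibrium error at t−1, so the smallest nesting specification is
ARDL(1,1). Fitting ARDL(1,0) still recovers the long-run slopes (the
cointegrating vector is superconsistent), but attenuates the adjustment
speed θ noticeably (child: mean −0.135 vs a true −0.1805 at T = 2,000).
Long-run recovery checks therefore use ARDL(1,0) and adjustment-speed
checks use ARDL(1,1).

## Numerical choices

* OLS via `numpy.linalg.lstsq`; rank checked by pivoted QR, with the
  collinear columns named in the error.
* Degeneracy tolerance |1 − Σα| < 10⁻⁸; inversion slope tolerance 10⁻¹⁰.
* Information criteria from the Gaussian log-likelihood; grid search uses
  the concentrated form n·log(SSR/n) + penalty·k on the common sample.
* RNG: `numpy` `SeedSequence` spawning, one independent stream per
  simulator stage, so `generate_panel` equals the composition of
  `simulate_regressors` and `simulate_outcome` and is a pure function of
  the configuration.
* Report JSON is written with sorted keys and no timestamps, so identical
  configurations produce byte-identical artifacts.

## Known limitations

* p-values of the unit-root test are interpolated from a 12-point quantile
  grid — adequate for 1/5/10% verdicts, not for precision tail work.
* The bounds critical values are asymptotic (simulated at T = 1,000); at
  T ≈ 100 the test over-rejects by roughly half a percentage point, within
  the tolerance the calibration suite enforces, but small-sample bounds are
  not provided.
* Single-instrument inversion answers a counterfactual per regressor; a
  joint adjustment of several instruments would need less of each, and no
  uncertainty bands accompany the required levels.
* No structural-break diagnostics, Johansen-type system estimation, or
  dummy-variable machinery.
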