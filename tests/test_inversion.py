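"""Target inversion: glide paths, baselines, single-variable solves,
binding rule and forward-forecast verification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

import macromort as mm
from macromort.panel import LOG_SCALE, REGRESSORS


@pytest.fixture(scope="module")
def fitted(default_panel):
    fits = {
        o: mm.to_ecm(mm.fit_ardl(default_panel, mm.ARDLSpec(p=1, q=1), o))
        for o in ("maternal", "child")
    }
    baseline = mm.baseline_paths(default_panel, 2030)
    return default_panel, fits, baseline


def random_long_run(rng, outcome="maternal"):
    slopes = {r: rng.uniform(0.05, 0.5) * rng.choice([-1, 1]) for r in REGRESSORS}
    return mm.LongRunParams(
        outcome=outcome,
        intercept=rng.uniform(-2, 8),
        intercept_se=0.1,
        slopes=slopes,
        se={r: 0.1 for r in REGRESSORS},
        p_values={r: 0.5 for r in REGRESSORS},
        stars={r: "" for r in REGRESSORS},
    )


class TestGlidePath:
    def test_flat_when_target_equals_last_observed(self):
        path = mm.glide_path(100.0, 100.0, range(2020, 2031))
        np.testing.assert_allclose(path.to_numpy(), 100.0)

    def test_geometric_midpoint(self):
        path = mm.glide_path(100.0, 25.0, [2020, 2021, 2022])
        assert path.loc[2021] == pytest.approx(50.0)

    def test_matches_pointwise_log_interpolation(self):
        years = np.arange(2020, 2031)
        path = mm.glide_path(512.0, 70.0, years)
        expected = np.exp(
            np.log(512.0)
            + (years - 2020) / 10 * (np.log(70.0) - np.log(512.0))
        )
        np.testing.assert_allclose(path.to_numpy(), expected, rtol=1e-12)

    @pytest.mark.parametrize("last,target", [(0.0, 50.0), (100.0, -1.0)])
    def test_nonpositive_endpoints_rejected(self, last, target):
        with pytest.raises(mm.ConfigurationError):
            mm.glide_path(last, target, range(2020, 2031))


class TestBaselinePaths:
    def test_linear_history_extrapolates_exactly(self):
        T = 20
        t = np.arange(T, dtype=float)
        w = pd.DataFrame(
            {
                "maternal": 6.0 - 0.03 * t,
                "child": 5.0 - 0.02 * t,
                "health": 4.0 + 0.08 * t,
                "gfc": 2.0 + 0.05 * t,
                "unemployment": 8.0 + 0.1 * t,
                "cons": 2.0,
                "corruption": -1.0 - 0.01 * t,
            },
            index=pd.RangeIndex(T, name="year") + 2001,
        )
        panel = mm.MacroPanel.from_working(w)
        paths = mm.baseline_paths(panel, 2030)
        pw = paths.working()
        assert pw.loc[2030, "health"] == pytest.approx(4.0 + 0.08 * 29, abs=1e-9)
        assert pw.loc[2030, "cons"] == pytest.approx(2.0, abs=1e-9)
        assert (paths.provenance.loc[panel.last_year] == "observed").all()
        assert (
            paths.provenance.loc[panel.last_year + 1:] == "baseline-extrapolated"
        ).all().all()

    def test_matches_closed_form_trend_oracle(self, fitted):
        panel, _, paths = fitted
        w = panel.working()
        years = panel.years.astype(float)
        for r in REGRESSORS:
            yv = w[r].to_numpy()
            xb, yb = years.mean(), yv.mean()
            slope = ((years - xb) * (yv - yb)).sum() / ((years - xb) ** 2).sum()
            proj = yb + slope * (2030 - xb)
            assert paths.working().loc[2030, r] == pytest.approx(proj, abs=1e-9)

    def test_short_history_raises(self, toy_working):
        short = mm.MacroPanel.from_working(toy_working)
        paths = mm.baseline_paths(short, 2030)  # 10 years is enough
        del paths
        with pytest.raises(mm.ConfigurationError):
            mm.baseline_paths(short, short.last_year)  # horizon not beyond window


class TestInvertSingle:
    def test_one_unknown_linear_solve(self):
        # intercept 0, slope -1 on a level-scale variable, target -3 -> x = 3
        lr = mm.LongRunParams(
            outcome="maternal",
            intercept=0.0,
            intercept_se=0.0,
            slopes={"health": 0.0, "gfc": 0.0, "unemployment": -1.0,
                    "cons": 0.0, "corruption": 0.0},
            se={r: 0.0 for r in REGRESSORS},
            p_values={r: 1.0 for r in REGRESSORS},
            stars={r: "" for r in REGRESSORS},
        )
        values = pd.DataFrame(
            {r: np.ones(3) for r in REGRESSORS},
            index=pd.Index([2020, 2021, 2022], name="year"),
        )
        base = mm.RegressorPath(values, values.astype(str))
        # maternal is log scale: target exp(-3) gives working target -3
        res = mm.invert_single(lr, float(np.exp(-3.0)), 2022, "unemployment", base)
        assert res.value == pytest.approx(3.0, abs=1e-10)

    def test_agrees_with_bisection_oracle(self, fitted):
        panel, fits, baseline = fitted
        rng = np.random.default_rng(21)
        for _ in range(20):
            lr = random_long_run(rng)
            var = rng.choice(REGRESSORS)
            target = float(rng.uniform(30, 300))
            res = mm.invert_single(lr, target, 2030, var, baseline)

            base_w = baseline.working().loc[2030]

            def forward(x_w):
                xs = dict(base_w)
                xs[var] = x_w
                return lr.predict(xs) - np.log(target)

            root = optimize.brentq(
                forward,
                res.working_value - 10,
                res.working_value + 10,
                xtol=1e-13,
                rtol=1e-14,
            )
            assert res.working_value == pytest.approx(root, rel=1e-12, abs=1e-12)

    def test_vanishing_slope_raises(self, fitted):
        _, _, baseline = fitted
        rng = np.random.default_rng(22)
        lr = random_long_run(rng)
        lr.slopes["health"] = 0.0
        with pytest.raises(mm.NonInvertibleError):
            mm.invert_single(lr, 70.0, 2030, "health", baseline)

    def test_extreme_requirement_flagged_not_suppressed(self, fitted):
        _, _, baseline = fitted
        rng = np.random.default_rng(23)
        lr = random_long_run(rng)
        lr.slopes["health"] = -1e-3  # tiny but invertible slope
        res = mm.invert_single(lr, 1e-6, 2030, "health", baseline)
        assert np.isfinite(res.working_value)
        assert res.value > 0  # log-scale back-transform is positive always
        assert res.extreme


class TestInvertAll:
    def test_table_has_milestone_by_indicator_shape(self, fitted):
        panel, fits, baseline = fitted
        sched = mm.TargetSchedule()
        last = {o: float(panel.data[o].iloc[-1]) for o in fits}
        inv = mm.invert_all(fits, sched, baseline, last, panel.last_year)
        assert list(inv.table.index) == [2025, 2027, 2030]
        assert list(inv.table.columns) == ["maternal", "child", *REGRESSORS]
        assert inv.table.notna().all().all()

    def test_identical_equations_give_identical_requirements(self, fitted):
        panel, fits, baseline = fitted
        twin = {"maternal": fits["maternal"], "child": fits["maternal"]}
        sched = mm.TargetSchedule(targets={"maternal": 70.0, "child": 70.0})
        last = float(panel.data["maternal"].iloc[-1])
        inv = mm.invert_all(
            twin, sched, baseline, {"maternal": last, "child": last}, panel.last_year
        )
        for r in REGRESSORS:
            one = mm.invert_single(
                fits["maternal"].long_run, float(inv.glide_paths["maternal"].loc[2030]),
                2030, r, baseline,
            )
            assert inv.table.loc[2030, r] == pytest.approx(one.value, rel=1e-12)

    def test_binding_rule_matches_enumeration(self, fitted):
        panel, fits, baseline = fitted
        sched = mm.TargetSchedule()
        last = {o: float(panel.data[o].iloc[-1]) for o in fits}
        inv = mm.invert_all(fits, sched, baseline, last, panel.last_year)
        for year in sched.milestone_years:
            for r in REGRESSORS:
                sols = {}
                for o, f in fits.items():
                    try:
                        sols[o] = mm.invert_single(
                            f.long_run, float(inv.glide_paths[o].loc[year]),
                            year, r, baseline,
                        ).value
                    except mm.NonInvertibleError:
                        pass
                pick = min(sols.values()) if r == "unemployment" else max(sols.values())
                assert inv.table.loc[year, r] == pytest.approx(pick, rel=1e-12)
                assert inv.binding.loc[year, r] in sols

    def test_joint_adjustment_hits_target_with_smaller_moves(self, fitted):
        panel, fits, baseline = fitted
        rng = np.random.default_rng(31)
        lr = random_long_run(rng)
        target = 70.0
        levels, s = mm.invert_joint(lr, target, 2030, baseline)
        xs = {
            r: (np.log(levels[r]) if r in LOG_SCALE else levels[r])
            for r in REGRESSORS
        }
        assert float(np.exp(lr.predict(xs))) == pytest.approx(target, rel=1e-8)
        # each instrument moves by exactly |s| on the working scale, no more
        # than the single-instrument solve for that variable would require
        base_w = baseline.working().loc[2030]
        for r in REGRESSORS:
            single = mm.invert_single(lr, target, 2030, r, baseline)
            assert abs(xs[r] - base_w[r]) <= abs(single.working_value - base_w[r]) + 1e-9

    def test_more_ambitious_target_demands_more_health_spending(self, fitted):
        # with a negative long-run health slope, lowering the maternal
        # target cannot decrease the required expenditure
        panel, fits, baseline = fitted
        fit = fits["maternal"]
        if fit.long_run.slopes["health"] >= 0:
            pytest.skip("sampled fit has a positive health slope")
        hi = mm.invert_single(fit.long_run, 70.0, 2030, "health", baseline)
        lo = mm.invert_single(fit.long_run, 50.0, 2030, "health", baseline)
        assert lo.value >= hi.value


class TestForwardForecast:
    def test_long_run_fixed_point_is_exact(self, fitted):
        # paths satisfying the long-run equation reproduce the target exactly
        panel, fits, baseline = fitted
        fit = fits["maternal"]
        target = 70.0
        req = mm.invert_single(fit.long_run, target, 2030, "health", baseline)
        values = baseline.values.copy()
        values["health"] = req.value
        path = mm.RegressorPath(values, baseline.provenance)
        fc = mm.forward_forecast(fit, path, 2030)
        assert float(fc.long_run.iloc[-1]) == pytest.approx(target, rel=1e-10)

    def test_dynamic_converges_geometrically_on_constant_paths(self, fitted):
        panel, fits, baseline = fitted
        fit = fits["maternal"]
        values = pd.DataFrame(
            {r: baseline.values[r].iloc[0] for r in REGRESSORS},
            index=pd.Index(range(panel.last_year, 2101), name="year"),
        )
        path = mm.RegressorPath(values, values.astype(str))
        fc = mm.forward_forecast(fit, path, 2100)
        x_w = path.working().iloc[0]
        y_star = fit.long_run.predict(x_w)
        gap = np.log(fc.dynamic.to_numpy()) - y_star
        # after the distributed lags wash out, the gap contracts by (1+theta)
        ratios = gap[10:40] / gap[9:39]
        np.testing.assert_allclose(ratios, 1 + fit.theta, atol=1e-6)
        # and the horizon gap is bounded by the unadjusted equilibrium error
        assert abs(gap[-1]) <= abs(gap[9]) * abs(1 + fit.theta) ** (len(gap) - 10) + 1e-8

    def test_round_trip_reproduces_glide_target(self, fitted):
        # inversion followed by long-run forward substitution returns the
        # target; checked across randomized fits
        panel, fits, baseline = fitted
        rng = np.random.default_rng(24)
        for _ in range(100):
            lr = random_long_run(rng)
            target = float(rng.uniform(30, 400))
            var = rng.choice(REGRESSORS)
            req = mm.invert_single(lr, target, 2030, var, baseline)
            xs = dict(baseline.working().loc[2030])
            xs[var] = req.working_value
            y = lr.predict(xs)
            assert np.exp(y) == pytest.approx(target, rel=1e-8)

    def test_path_gap_raises_alignment_error(self, fitted):
        panel, fits, baseline = fitted
        values = baseline.values.drop(index=2027)
        with pytest.raises(mm.AlignmentError):
            mm.RegressorPath(values, baseline.provenance.drop(index=2027))
        with pytest.raises(mm.AlignmentError):
            mm.forward_forecast(fits["maternal"], baseline, 2040)


class TestTargetSchedule:
    def test_defaults_are_the_sdg_targets(self):
        sched = mm.TargetSchedule()
        assert sched.targets["maternal"] == 70.0
        assert sched.targets["child"] == 25.0
        assert sched.milestone_years == (2025, 2027, 2030)

    @given(st.floats(min_value=-10, max_value=0))
    @settings(derandomize=True, max_examples=20)
    def test_nonpositive_targets_rejected(self, bad):
        with pytest.raises(mm.ConfigurationError):
            mm.TargetSchedule(targets={"maternal": bad, "child": 25.0})

    def test_milestones_beyond_horizon_rejected(self):
        with pytest.raises(mm.ConfigurationError):
            mm.TargetSchedule(milestone_years=(2025, 2035))
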