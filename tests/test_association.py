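"""First-stage OLS and the Cox partial-likelihood machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from vitdmr import (
    check_proportionality,
    cox_score_test,
    fit_cox,
    fit_linear,
    rate_table,
)
from vitdmr.association import _loglik_parts, _prepare


class TestFitLinear:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = fit_linear(3.0 + 2.0 * x, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-8)

    def test_matches_closed_form_least_squares(self, rng):
        """Slope, SE, R2 against the textbook expressions computed
        directly from sums of squares."""
        x = rng.normal(size=40)
        y = 1.0 + 0.5 * x + rng.normal(0, 2.0, size=40)
        fit = fit_linear(y, x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        resid = y - (y.mean() - slope * x.mean()) - slope * x
        s2 = (resid**2).sum() / (len(x) - 2)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.slope_se == pytest.approx(np.sqrt(s2 / sxx), rel=1e-10)
        sst = ((y - y.mean()) ** 2).sum()
        assert fit.r2 == pytest.approx(1 - (resid**2).sum() / sst, rel=1e-10)

    def test_f_r2_identity(self, rng):
        for n in (20, 200, 1782):
            x = rng.normal(size=n)
            y = 0.2 * x + rng.normal(size=n)
            fit = fit_linear(y, x)
            assert fit.f_stat == pytest.approx(
                fit.r2 * (fit.n - 2) / (1 - fit.r2), rel=1e-8
            )

    def test_listwise_deletion_and_adjustment(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = 1.0 + 0.8 * x + 0.5 * z + rng.normal(0, 0.5, size=50)
        y[3] = np.nan
        fit = fit_linear(y, x, covariates=pd.DataFrame({"z": z}))
        assert fit.n == 49
        # adjusted slope equals the normal-equation solution
        keep = ~np.isnan(y)
        X = np.column_stack([np.ones(49), x[keep], z[keep]])
        beta = np.linalg.lstsq(X, y[keep], rcond=None)[0]
        assert fit.adjusted_slope == pytest.approx(beta[1], rel=1e-10)

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear(np.arange(10.0), np.ones(10))

    def test_jackknife_slope_se_tracks_ols_se(self, rng):
        """On homoskedastic data the delete-one jackknife SE of the slope
        agrees with the model-based OLS SE, and it matches an explicit
        leave-one-out recomputation exactly."""
        from vitdmr import jackknife_slope_se

        n = 400
        x = rng.normal(size=n)
        y = 2.0 + 1.5 * x + rng.normal(0, 1.0, size=n)
        jk = jackknife_slope_se(y, x)
        ols = fit_linear(y, x).slope_se
        assert jk == pytest.approx(ols, rel=0.15)
        # brute-force leave-one-out on a small subset
        xs, ys = x[:30], y[:30]
        loo = np.array(
            [
                np.polyfit(np.delete(xs, i), np.delete(ys, i), 1)[0]
                for i in range(30)
            ]
        )
        brute = np.sqrt(29 / 30 * ((loo - loo.mean()) ** 2).sum())
        assert jackknife_slope_se(ys, xs) == pytest.approx(brute, rel=1e-8)


def _naive_breslow_loglik(beta, times, events, x):
    """Handwritten Breslow partial likelihood via explicit loops."""
    ll = 0.0
    for tj in sorted(set(times[events == 1])):
        members = np.flatnonzero((times == tj) & (events == 1))
        risk = np.flatnonzero(times >= tj)
        ll += beta * x[members].sum() - len(members) * np.log(
            np.exp(beta * x[risk]).sum()
        )
    return ll


class TestFitCox:
    def test_null_exposure_recovers_hr_one(self, rng):
        n = 5000
        x = rng.normal(size=n)
        t = rng.exponential(100.0, size=n)
        e = (t < 20).astype(int)
        t = np.minimum(t, 20.0)
        fit = fit_cox(t, e, x)
        assert abs(fit.coef) < 3 * fit.coef_se
        assert fit.converged

    def test_matches_brute_force_on_tiny_data(self):
        """Six subjects, no ties: Newton-Raphson agrees with direct
        maximization of the handwritten partial likelihood to 1e-6."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5])
        fit = fit_cox(times, events, x)
        res = optimize.minimize_scalar(
            lambda b: -_naive_breslow_loglik(b, times, events, x),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)
        assert fit.converged

    def test_breslow_handles_ties_like_handwritten_likelihood(self):
        times = np.array([2.0, 2.0, 2.0, 5.0, 5.0, 7.0, 8.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, -1.0, 0.5, 1.5, -0.5, 0.0])
        fit = fit_cox(times, events, x, ties="breslow")
        res = optimize.minimize_scalar(
            lambda b: -_naive_breslow_loglik(b, times, events, x),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coef == pytest.approx(res.x, abs=1e-6)

    def test_agrees_with_lifelines_on_tiefree_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 800
        x = rng.normal(size=n)
        age = rng.normal(55, 7, size=n)
        t = rng.exponential(
            1 / (0.02 * np.exp(0.4 * x + 0.01 * (age - 55))), size=n
        )
        e = (t < 15).astype(int)
        t = np.minimum(t, 15.0) + rng.uniform(0, 1e-9, n)
        fit = fit_cox(t, e, x, pd.DataFrame({"age": age}))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x, "age": age}), "t", "e"
        )
        assert fit.coefs == pytest.approx(cph.params_.to_numpy(), abs=1e-6)
        assert fit.ses == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-6)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_efron_agrees_with_lifelines_on_tied_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 400
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(1 / (0.05 * np.exp(0.5 * x)), size=n))
        e = (t < 15).astype(int)
        t = np.minimum(t, 15.0)
        fit = fit_cox(t, e, x, ties="efron")
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert fit.coef == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert fit.coef_se == pytest.approx(
            float(cph.standard_errors_.iloc[0]), abs=1e-6
        )

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(10, size=n) + rng.uniform(0, 1e-6, n)
        e = (t < 12).astype(int)
        t = np.minimum(t, 12.0)
        a = fit_cox(t, e, x, ties="breslow")
        b = fit_cox(t, e, x, ties="efron")
        assert a.coef == pytest.approx(b.coef, abs=1e-9)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_covariate_rescaling_invariance(self, rng):
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.3 * x)), size=n)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10.0)
        a = fit_cox(t, e, x)
        b = fit_cox(t, e, 10.0 * x)
        assert b.coef == pytest.approx(a.coef / 10.0, rel=1e-8)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-9)

    def test_known_log_hazard_recovered_over_replicates(self):
        """Simulation with log-HR 0.3: the mean estimate over 100
        replicates of n = 5000 sits within 3 Monte-Carlo SEs of truth."""
        gamma = 0.3
        rng = np.random.default_rng(77)
        ests = []
        for _ in range(100):
            x = rng.normal(size=5000)
            t = rng.exponential(1 / (0.01 * np.exp(gamma * x)), size=5000)
            e = (t < 20).astype(int)
            t = np.minimum(t, 20.0)
            ests.append(fit_cox(t, e, x).coef)
        ests = np.asarray(ests)
        assert abs(ests.mean() - gamma) < 3 * ests.std(ddof=1) / 10

    def test_score_test_equals_logrank(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test

        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(0.6 * x)), size=n)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10.0) + rng.uniform(0, 1e-9, n)
        chi2, p = cox_score_test(t, e, x)
        lr = logrank_test(t[x == 0], t[x == 1], e[x == 0], e[x == 1])
        assert chi2 == pytest.approx(lr.test_statistic, rel=1e-10)
        assert p == pytest.approx(lr.p_value, rel=1e-10)

    def test_perfect_separation_flags_nonconvergence(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])  # monotone likelihood
        fit = fit_cox(times, events, x)
        assert not fit.converged

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox([1.0, 2.0], [0, 0], [0.5, 1.0])


class TestProportionality:
    def test_null_p_values_are_uniform(self):
        """Data generated under exact proportional hazards: the Schoenfeld
        test p-values over replicates pass a KS uniformity check."""
        rng = np.random.default_rng(5150)
        ps = []
        for _ in range(150):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(1 / (0.05 * np.exp(0.4 * x)), size=n)
            e = (t < 12).astype(int)
            t = np.minimum(t, 12.0)
            fit = fit_cox(t, e, x)
            ps.append(check_proportionality(fit, t, e, x)["exposure"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_reversing_hazard(self):
        """An exposure whose effect flips sign mid-follow-up violates
        proportionality and is flagged at large n."""
        rng = np.random.default_rng(88)
        n = 6000
        x = (rng.random(n) < 0.5).astype(float)
        # piecewise exponential: strong positive effect before t=5,
        # strong negative after
        t1 = rng.exponential(1 / (0.10 * np.exp(1.2 * x)), size=n)
        t2 = 5.0 + rng.exponential(1 / (0.10 * np.exp(-1.2 * x)), size=n)
        t = np.where(t1 < 5.0, t1, t2)
        e = (t < 15).astype(int)
        t = np.minimum(t, 15.0)
        fit = fit_cox(t, e, x)
        p = check_proportionality(fit, t, e, x)["exposure"]
        assert p < 0.001

    def test_residuals_sum_to_zero_at_optimum(self, rng):
        """The score equations vanish at the fitted coefficients, i.e.
        Schoenfeld residuals sum to ~0 across events."""
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.3 * x)), size=n)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10.0)
        fit = fit_cox(t, e, x)
        tt, ee, X, _ = _prepare(t, e, x, None, "x", None)
        _, score, _ = _loglik_parts(fit.coefs, tt, ee, X, "breslow")
        assert np.max(np.abs(score)) < 1e-6

    def test_too_few_events_reported_missing(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0])
        x = np.array([0.5, -0.5, 1.0, 0.0])
        fit = fit_cox(t, e, x)
        out = check_proportionality(fit, t, e, x)
        assert np.isnan(out["exposure"])


class TestRateTable:
    def test_rates(self):
        rows = rate_table(
            ["a", "b", "ref"], [10, 0, 1091], [1000.0, 500.0, 112_358.0],
            n=[100, 50, 6468],
        )
        assert rows[0].rate_per_1000 == 10.00
        assert rows[1].rate_per_1000 == 0.00
        # back-solved person-years reproduce the reference-row rate
        assert rows[2].rate_per_1000 == 9.71
        assert rows[2].cases == 1091 and rows[2].n == 6468

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            rate_table(["a"], [-1], [10.0])
        with pytest.raises(ValueError):
            rate_table(["a"], [1], [0.0])
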