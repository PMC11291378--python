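from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from dwisurv.survival import (
    ConvergenceError,
    CoxPH,
    StepFunction,
    as_time_event,
    c_harrell,
    cox_fit,
    cox_loglik,
    km,
    model_survival_curves,
    reverse_km,
)

lifelines = pytest.importorskip("lifelines")


def _brute_loglik(beta, x, time, event):
    """Breslow partial log-likelihood by explicit risk-set enumeration."""
    x = np.asarray(x, float)
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = time >= time[i]
        ll += float(x[i] @ np.atleast_1d(beta)) - np.log(
            np.exp(x[risk] @ np.atleast_1d(beta)).sum()
        )
    return ll


class TestAsTimeEvent:
    def test_tuple(self):
        t, e = as_time_event(([1.0, 2.0], [1, 0]))
        np.testing.assert_array_equal(t, [1.0, 2.0])
        np.testing.assert_array_equal(e, [1, 0])

    def test_dataframe_time_months(self):
        df = pd.DataFrame({"time_months": [3.0, 4.0], "event": [0, 1]})
        t, e = as_time_event(df)
        np.testing.assert_array_equal(t, [3.0, 4.0])
        np.testing.assert_array_equal(e, [0, 1])

    def test_nonpositive_time_raises(self):
        with pytest.raises(ValueError, match="positive"):
            as_time_event(([0.0, 1.0], [1, 1]))

    def test_bad_type_raises(self):
        with pytest.raises(TypeError):
            as_time_event([1.0, 2.0])


class TestStepFunction:
    def test_right_continuous_with_flat_extension(self):
        f = StepFunction([1.0, 3.0], [0.8, 0.5], initial=1.0)
        np.testing.assert_allclose(
            f([0.0, 0.999, 1.0, 2.0, 3.0, 10.0]), [1.0, 1.0, 0.8, 0.8, 0.5, 0.5]
        )

    def test_scalar_call(self):
        f = StepFunction([2.0], [0.5])
        assert f(5.0) == 0.5

    def test_unsorted_knots_raise(self):
        with pytest.raises(ValueError):
            StepFunction([2.0, 1.0], [0.5, 0.4])


class TestCoxFit:
    def test_toy_matches_1d_brute_force(self):
        # x = {0,1,0,1} has an interior maximum
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        model = CoxPH().fit(x, (time, event))
        ref = minimize_scalar(
            lambda b: -_brute_loglik(b, x, time, event),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert model.coef_[0] == pytest.approx(ref.x, abs=1e-6)
        assert model.loglik_ == pytest.approx(-ref.fun, abs=1e-10)

    def test_matches_lifelines_untied(self, rng):
        n = 80
        X = rng.standard_normal((n, 3))
        time = rng.exponential(10, n) + rng.uniform(0, 1e-6, n)
        event = rng.uniform(size=n) < 0.7
        model = CoxPH().fit(X, (time, event))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = time, event.astype(int)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(model.coef_, cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(model.se_, cph.standard_errors_.to_numpy(), atol=1e-6)
        assert model.loglik_ == pytest.approx(cph.log_likelihood_, abs=1e-8)

    def test_matches_lifelines_efron_with_ties(self, rng):
        n = 60
        X = rng.standard_normal((n, 2))
        time = rng.integers(1, 8, n).astype(float)  # heavy ties
        event = rng.uniform(size=n) < 0.8
        model = CoxPH(ties="efron").fit(X, (time, event))
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = time, event.astype(int)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")  # lifelines uses Efron
        np.testing.assert_allclose(model.coef_, cph.params_.to_numpy(), atol=1e-6)
        assert model.loglik_ == pytest.approx(cph.log_likelihood_, abs=1e-7)

    def test_breslow_ties_hand_computed(self):
        # two events tied at t=1 (x=1 and x=0), one later event (x=0):
        # Breslow: ll = (b + 0) - 2*log(2e^b + 2) + 0 - log(2)... with 4th
        # patient censored after; verify against explicit formula
        x = np.array([[1.0], [0.0], [0.0], [1.0]])
        time = np.array([1.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 1, 0])

        def breslow(b):
            denom1 = 2 * np.exp(b) + 2
            denom2 = np.exp(b) + 1
            return b - 2 * np.log(denom1) - np.log(denom2)

        model = CoxPH(ties="breslow").fit(x, (time, event))
        ref = minimize_scalar(lambda b: -breslow(b), bounds=(-10, 10),
                              method="bounded", options={"xatol": 1e-10})
        assert model.coef_[0] == pytest.approx(ref.x, abs=1e-6)
        assert model.loglik_ == pytest.approx(breslow(model.coef_[0]), abs=1e-10)

    def test_separation_raises(self):
        # all group-1 events strictly before all group-0 events: monotone
        # likelihood, no finite maximiser
        x = np.array([[1.0], [1.0], [0.0], [0.0]])
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        with pytest.raises(ConvergenceError, match="separation|diverge"):
            CoxPH().fit(x, (time, event))

    def test_constant_column_raises(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant"):
            CoxPH().fit(x, (np.arange(1.0, 6.0), np.ones(5, int)))

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            CoxPH().fit(np.arange(4.0)[:, None], (np.arange(1.0, 5.0), np.zeros(4, int)))

    def test_beta_recovery_large_n(self):
        from dwisurv.synthetic import simulate_survival_features

        X, y = simulate_survival_features(800, 1, beta=np.log(2), seed=5)
        model = CoxPH().fit(X, y)
        assert model.coef_[0] == pytest.approx(np.log(2), abs=0.12)

    def test_wald_ci_coverage(self):
        # 200 parametric replicates; 95% Wald interval covers the truth
        # between 90% and 99% of the time
        from dwisurv.synthetic import simulate_survival_features

        beta = np.log(2)
        covered = 0
        for rep in range(200):
            X, y = simulate_survival_features(150, 1, beta=beta, seed=10_000 + rep)
            m = CoxPH().fit(X, y)
            lo = m.coef_[0] - 1.959963984540054 * m.se_[0]
            hi = m.coef_[0] + 1.959963984540054 * m.se_[0]
            covered += lo <= beta <= hi
        assert 0.90 <= covered / 200 <= 0.99

    def test_cox_fit_wrapper_subset(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
        y = (rng.exponential(5, 40) + 0.01, np.ones(40, int))
        m = cox_fit(X, y, subset=["b", "a"])
        assert m.param_names_ == ["b", "a"]
        with pytest.raises(KeyError):
            cox_fit(X, y, subset=["nope"])

    def test_hazard_ratios_property(self, rng):
        X = rng.standard_normal((50, 2))
        y = (rng.exponential(5, 50) + 0.01, np.ones(50, int))
        m = CoxPH().fit(X, y)
        np.testing.assert_allclose(m.hazard_ratios_, np.exp(m.coef_))


class TestCoxLoglik:
    def test_zero_beta_closed_form(self, rng):
        # at beta = 0 every factor is 1/|risk set|
        n = 30
        time = rng.uniform(1, 20, n)
        event = rng.uniform(size=n) < 0.6
        if event.sum() == 0:
            event[0] = True
        X = rng.standard_normal((n, 2))
        ref = -sum(np.log((time >= t).sum()) for t, e in zip(time, event) if e)
        ll = cox_loglik(np.zeros(2), X, (time, event))
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_matches_brute_force_at_arbitrary_beta(self, rng):
        n = 25
        time = rng.uniform(1, 20, n)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        X = rng.standard_normal((n, 2))
        beta = np.array([0.4, -1.1])
        ll = cox_loglik(beta, X, (time, event))
        assert ll == pytest.approx(_brute_loglik(beta, X, time, event), abs=1e-9)

    def test_consistent_with_fit(self, rng):
        X = rng.standard_normal((40, 2))
        y = (rng.exponential(10, 40) + 0.01, np.ones(40, int))
        m = CoxPH().fit(X, y)
        assert cox_loglik(m.coef_, X, y) == pytest.approx(m.loglik_, abs=1e-9)

    def test_zero_events_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="zero events"):
            ll = cox_loglik([0.5], np.ones((3, 1)), ([1.0, 2.0, 3.0], [0, 0, 0]))
        assert ll == 0.0

    def test_empty_data_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            ll = cox_loglik([0.5], np.empty((0, 1)), (np.empty(0), np.empty(0, int)))
        assert ll == 0.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            cox_loglik([0.5, 0.2], np.ones((3, 1)), ([1.0, 2.0, 3.0], [1, 1, 1]))


class TestCHarrell:
    def test_perfectly_concordant(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        lp = np.array([4.0, 3.0, 2.0, 1.0])  # highest risk dies first
        assert c_harrell(lp, time, np.ones(4, int)) == 1.0

    def test_all_tied_predictors(self):
        time = np.array([1.0, 2.0, 3.0])
        assert c_harrell(np.zeros(3), time, np.ones(3, int)) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = 25
            time = rng.integers(1, 15, n).astype(float)
            event = rng.uniform(size=n) < 0.6
            lp = rng.standard_normal(n)
            if not ((time[:, None] < time[None, :]) & event[:, None]).any():
                continue
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if event[i] and time[i] < time[j]:
                        den += 1
                        if lp[i] > lp[j]:
                            num += 1
                        elif lp[i] == lp[j]:
                            num += 0.5
            assert c_harrell(lp, time, event) == pytest.approx(num / den, abs=1e-12)

    def test_matches_lifelines(self, rng):
        n = 60
        time = rng.uniform(1, 20, n)
        event = rng.uniform(size=n) < 0.7
        lp = rng.standard_normal(n)
        from lifelines.utils import concordance_index

        ref = concordance_index(time, -lp, event)
        assert c_harrell(lp, time, event) == pytest.approx(ref, abs=1e-12)

    def test_flip_symmetry(self, rng):
        time = rng.uniform(1, 10, 30)
        event = np.ones(30, int)
        lp = rng.standard_normal(30)
        assert c_harrell(lp, time, event) + c_harrell(-lp, time, event) == pytest.approx(1.0)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            c_harrell([1.0, 2.0], [5.0, 5.0], [1, 1])


class TestKM:
    def test_hand_computed_ten_patients(self):
        time = [2, 4, 4, 6, 8, 9, 10, 12, 13, 15]
        event = [1, 1, 1, 0, 1, 0, 1, 0, 1, 0]
        res = km((np.asarray(time, float), np.asarray(event)))
        expected = [
            Fraction(9, 10),
            Fraction(9, 10) * Fraction(7, 9),
            Fraction(7, 10) * Fraction(5, 6),
            Fraction(7, 12) * Fraction(3, 4),
            Fraction(7, 16) * Fraction(1, 2),
        ]
        np.testing.assert_array_equal(res.survival.knots, [2, 4, 8, 10, 13])
        np.testing.assert_allclose(res.survival.values, [float(f) for f in expected],
                                   rtol=1e-14)
        assert res.median == 10.0  # first time S <= 0.5 (S(10) = 0.4375)
        np.testing.assert_array_equal(res.n_at_risk, [10, 9, 6, 4, 2])
        np.testing.assert_array_equal(res.n_events, [1, 2, 1, 1, 1])

    def test_matches_lifelines_curve(self, rng):
        n = 50
        time = rng.uniform(1, 30, n)
        event = rng.uniform(size=n) < 0.6
        res = km((time, event))
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        for t in res.survival.knots:
            assert res.survival(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_no_censoring_matches_empirical(self, rng):
        time = rng.uniform(1, 10, 40)
        res = km((time, np.ones(40, int)))
        for t in res.survival.knots:
            assert res.survival(t) == pytest.approx((time > t).mean(), abs=1e-12)

    def test_median_not_reached(self):
        res = km(([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0]))
        assert np.isinf(res.median)

    def test_ci_brackets_curve(self, rng):
        time = rng.uniform(1, 30, 60)
        event = rng.uniform(size=60) < 0.7
        res = km((time, event))
        assert np.all(res.lower.values <= res.survival.values + 1e-12)
        assert np.all(res.upper.values >= res.survival.values - 1e-12)

    def test_ci_matches_lifelines_greenwood_loglog(self, rng):
        time = rng.uniform(1, 30, 50)
        event = rng.uniform(size=50) < 0.6
        res = km((time, event))
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        ci = kmf.confidence_interval_
        for i, t in enumerate(res.survival.knots):
            row = ci.loc[t]
            assert res.lower.values[i] == pytest.approx(row.iloc[0], abs=1e-8)
            assert res.upper.values[i] == pytest.approx(row.iloc[1], abs=1e-8)

    def test_all_censored_gives_empty_curve(self):
        res = km(([1.0, 2.0], [0, 0]))
        assert res.survival.knots.size == 0
        assert np.isinf(res.median)


class TestReverseKM:
    def test_all_censored_median_followup(self):
        res = reverse_km(([12.0] * 6, [0] * 6))
        assert res.median == 12.0

    def test_flip_equivalence(self, rng):
        time = rng.uniform(1, 20, 30)
        event = (rng.uniform(size=30) < 0.5).astype(int)
        a = reverse_km((time, event))
        b = km((time, 1 - event))
        np.testing.assert_array_equal(a.survival.knots, b.survival.knots)
        np.testing.assert_array_equal(a.survival.values, b.survival.values)

    def test_toy(self):
        res = reverse_km(([10.0, 20.0], [1, 0]))
        # censoring "event" at t=20 with the t=10 death censored for follow-up
        assert res.median == 20.0


class TestModelCurves:
    def test_zero_lp_equals_baseline(self, rng):
        X = rng.standard_normal((40, 2))
        y = (rng.exponential(10, 40) + 0.01, np.ones(40, int))
        m = CoxPH().fit(X, y)
        curve = m.predict_survival_function(np.zeros((1, 2)))[0]
        H0 = m.baseline_cumhaz_
        np.testing.assert_allclose(curve.values, np.exp(-H0.values), rtol=1e-12)

    def test_higher_lp_lower_survival(self, rng):
        X = rng.standard_normal((50, 1))
        y = (rng.exponential(10, 50) + 0.01, np.ones(50, int))
        m = CoxPH().fit(X, y)
        sgn = np.sign(m.coef_[0])
        lo, hi = m.predict_survival_function(np.array([[-sgn], [sgn]]))
        assert np.all(hi.values <= lo.values + 1e-12)

    def test_breslow_baseline_matches_lifelines(self, rng):
        n = 60
        X = rng.standard_normal((n, 2))
        time = rng.exponential(10, n) + rng.uniform(0, 1e-6, n)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        m = CoxPH().fit(X, (time, event))
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = time, event
        cph = lifelines.CoxPHFitter(baseline_estimation_method="breslow").fit(df, "T", "E")
        ref = cph.baseline_cumulative_hazard_
        # lifelines' baseline is at the covariate mean; ours is at x = 0
        shift = float(np.exp(X.mean(axis=0) @ m.coef_))
        for t in m.baseline_cumhaz_.knots:
            assert m.baseline_cumhaz_(t) * shift == pytest.approx(
                float(ref.loc[ref.index <= t].iloc[-1, 0]), rel=1e-5
            )

    def test_wrapper(self, rng):
        X = rng.standard_normal((30, 1))
        y = (rng.exponential(5, 30) + 0.01, np.ones(30, int))
        m = CoxPH().fit(X, y)
        curves = model_survival_curves(m, X[:3])
        assert len(curves) == 3
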