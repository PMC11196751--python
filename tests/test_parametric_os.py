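import itertools
import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter, LogNormalAFTFitter, WeibullAFTFitter

from tgios.parametric_os import (
    AFT_FAMILIES,
    backward_eliminate,
    cox_univariate_screen,
    fit_parametric_survival,
    km_estimate,
    predict_parametric_curves,
)


def brute_force_km(times, events, query):
    """Independent oracle: survival at `query` directly from the definition,
    multiplying (1 - d/n) over every distinct event time <= query."""
    s = 1.0
    for u in sorted({t for t, e in zip(times, events) if e == 1}):
        if u > query:
            break
        n_at_risk = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1 - d / n_at_risk
    return s


class TestKaplanMeier:
    def test_worked_example(self):
        km = km_estimate([1, 2, 3], [1, 1, 0])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3])
        np.testing.assert_allclose(km.evaluate([0.5, 1.5, 2.5, 10]), [1, 2 / 3, 1 / 3, 1 / 3])

    def test_all_censored_flat_at_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert km.event_times.size == 0
        np.testing.assert_allclose(km.evaluate([0, 100]), [1, 1])

    def test_single_event(self):
        km = km_estimate([5.0], [1])
        np.testing.assert_allclose(km.evaluate([4.9, 5.0, 100.0]), [1, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    def test_exhaustive_small_instances_vs_oracle(self):
        # every event pattern over several <=6-patient time multisets,
        # including ties between events and censorings
        time_sets = [
            (1.0, 2.0, 3.0),
            (1.0, 1.0, 2.0, 5.0),
            (2.0, 2.0, 2.0, 4.0, 4.0),
            (1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
            (3.0, 3.0, 7.0, 7.0, 9.0, 9.0),
        ]
        for times in time_sets:
            for events in itertools.product([0, 1], repeat=len(times)):
                km = km_estimate(times, events)
                for q in sorted(set(times)) + [0.5, 10.0]:
                    assert km.evaluate([q])[0] == pytest.approx(
                        brute_force_km(times, events, q), abs=1e-12
                    )

    def test_matches_lifelines(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 80).round(1) + 0.1
        e = rng.integers(0, 2, 80)
        km = km_estimate(t, e)
        lf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0.0, t.max(), 37)
        np.testing.assert_allclose(
            km.evaluate(grid),
            lf.survival_function_at_times(grid).to_numpy(),
            atol=1e-12,
        )

    def test_product_limit_identity(self):
        km = km_estimate([1, 2, 2, 4, 9], [1, 1, 1, 0, 1])
        expected = np.cumprod(1 - km.n_events / km.at_risk)
        np.testing.assert_allclose(km.survival, expected)


def _surv_frame(times, events):
    return pd.DataFrame(
        {"patient_id": range(len(times)), "time_days": times, "event": events}
    )


class TestCoxScreening:
    def test_four_patient_grid_oracle(self):
        # interleaved groups so the partial-likelihood maximizer is finite
        # (x = (1,1,0,0) with times (1,2,3,4) is separated: MLE at +inf)
        x = np.array([1.0, 0.0, 1.0, 0.0])
        times = np.array([1.0, 2.0, 3.0, 4.0])

        def breslow_pl(beta):
            # independent oracle: direct sum over event times
            ll = 0.0
            for i in range(4):
                risk = [j for j in range(4) if times[j] >= times[i]]
                ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
            return ll

        grid = np.arange(-5, 5, 1e-4)
        oracle_beta = grid[np.argmax([breslow_pl(b) for b in grid])]
        feats = pd.DataFrame({"patient_id": range(4), "x": x})
        res = cox_univariate_screen(feats, _surv_frame(times, [1, 1, 1, 1]))[0]
        assert res.coef == pytest.approx(oracle_beta, abs=1e-4)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        n = 150
        x = rng.normal(size=n)
        t = np.exp(5 - 0.7 * x + rng.normal(0, 1, n))
        e = rng.integers(0, 2, n)
        e[0] = 1
        feats = pd.DataFrame({"patient_id": range(n), "x": x})
        res = cox_univariate_screen(feats, _surv_frame(t, e))[0]
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        # lifelines stops at a looser gradient tolerance than our Newton solve
        assert res.coef == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert res.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-5)

    def test_constant_feature_degenerate(self):
        feats = pd.DataFrame({"patient_id": range(4), "c": [2.0] * 4})
        res = cox_univariate_screen(feats, _surv_frame([1, 2, 3, 4], [1, 1, 0, 1]))[0]
        assert res.degenerate
        assert res.p_value == 1.0

    def test_missing_values_dropped_with_count(self):
        feats = pd.DataFrame(
            {"patient_id": range(6), "x": [1.0, np.nan, 0.5, np.nan, -1.0, 2.0]}
        )
        res = cox_univariate_screen(
            feats, _surv_frame([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        )[0]
        assert res.n == 4

    def test_screen_returns_one_result_per_feature(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(
            {"patient_id": range(30), "a": rng.normal(size=30), "b": rng.normal(size=30)}
        )
        res = cox_univariate_screen(feats, _surv_frame(rng.exponential(5, 30) + 0.1, [1] * 30))
        assert [r.covariate for r in res] == ["a", "b"]
        assert all(0 <= r.p_value <= 1 for r in res)


def _lognormal_aft_data(n, beta=-0.5, seed=0, censor_day=2000.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    logt = math.log(400) + beta * x + 0.8 * rng.standard_normal(n)
    t_event = np.exp(logt)
    time = np.minimum(t_event, censor_day)
    event = (t_event <= censor_day).astype(int)
    feats = pd.DataFrame({"patient_id": range(n), "logKG": x})
    return feats, _surv_frame(time, event)


class TestParametricFit:
    def test_exponential_closed_form_mle(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(120, 400)
        feats = pd.DataFrame({"patient_id": range(400)})
        m = fit_parametric_survival(
            feats, _surv_frame(t, [1] * 400), covariates=[], families=("exponential",)
        )
        # S(t) = exp(-exp(log t - b0)) => rate = exp(-b0); MLE = events / total time
        assert math.exp(-m.coefficients["intercept"]) == pytest.approx(
            400 / t.sum(), rel=1e-6
        )

    def test_lognormal_recovery_and_family_selection(self):
        feats, surv = _lognormal_aft_data(1000, beta=-0.5, seed=7)
        m = fit_parametric_survival(feats, surv)
        assert m.family == "lognormal"
        se = m.standard_errors()["logKG"]
        assert abs(m.coefficients["logKG"] - (-0.5)) < 3 * se

    def test_single_family_returned_regardless(self):
        feats, surv = _lognormal_aft_data(300, seed=2)
        m = fit_parametric_survival(feats, surv, families=("loglogistic",))
        assert m.family == "loglogistic"

    def test_loglik_matches_lifelines(self):
        feats, surv = _lognormal_aft_data(400, seed=9)
        df = pd.DataFrame(
            {
                "T": surv["time_days"],
                "E": surv["event"],
                "logKG": feats["logKG"],
            }
        )
        ours = fit_parametric_survival(feats, surv, families=("lognormal",))
        lf = LogNormalAFTFitter().fit(df, "T", "E")
        assert ours.log_likelihood == pytest.approx(lf.log_likelihood_, abs=1e-3)
        wb_ours = fit_parametric_survival(feats, surv, families=("weibull",))
        wb = WeibullAFTFitter().fit(df, "T", "E")
        assert wb_ours.log_likelihood == pytest.approx(wb.log_likelihood_, abs=1e-3)

    def test_aic_identity(self):
        feats, surv = _lognormal_aft_data(200, seed=4)
        m = fit_parametric_survival(feats, surv, families=("lognormal",))
        k = len(m.coefficients) + 1  # plus the scale parameter
        assert m.aic == pytest.approx(2 * k - 2 * m.log_likelihood)

    def test_empty_family_list_rejected(self):
        feats, surv = _lognormal_aft_data(50)
        with pytest.raises(ValueError):
            fit_parametric_survival(feats, surv, families=())

    def test_unknown_family_rejected(self):
        feats, surv = _lognormal_aft_data(50)
        with pytest.raises(ValueError, match="unknown"):
            fit_parametric_survival(feats, surv, families=("gamma",))


class TestBackwardElimination:
    def test_strong_model_unchanged(self):
        rng = np.random.default_rng(1)
        n = 800
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = np.exp(6 - 0.8 * x1 + 0.6 * x2 + 0.5 * rng.standard_normal(n))
        feats = pd.DataFrame({"patient_id": range(n), "x1": x1, "x2": x2})
        m = backward_eliminate(
            feats, _surv_frame(t, [1] * n), covariates=["x1", "x2"], alpha=0.01,
            families=("lognormal",),
        )
        assert sorted(m.covariates) == ["x1", "x2"]
        assert m.elimination_trace == []

    def test_noise_covariate_eliminated(self):
        removed = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n = 800
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            t = np.exp(6 - 0.8 * x + 0.6 * rng.standard_normal(n))
            feats = pd.DataFrame({"patient_id": range(n), "logKG": x, "noise": noise})
            m = backward_eliminate(
                feats, _surv_frame(t, [1] * n), covariates=["logKG", "noise"],
                alpha=0.01, families=("lognormal",),
            )
            if m.covariates == ["logKG"]:
                removed += 1
        assert removed >= 2

    def test_alpha_one_removes_nothing(self):
        feats, surv = _lognormal_aft_data(200, beta=0.0, seed=3)
        feats["junk"] = np.random.default_rng(0).normal(size=200)
        m = backward_eliminate(
            feats, surv, covariates=["logKG", "junk"], alpha=1.0,
            families=("lognormal",),
        )
        assert sorted(m.covariates) == ["junk", "logKG"]

    def test_column_order_invariance(self):
        rng = np.random.default_rng(8)
        n = 400
        a, b, c = rng.normal(size=(3, n))
        t = np.exp(6 - 0.7 * a + 0.4 * rng.standard_normal(n))
        surv = _surv_frame(t, [1] * n)
        f1 = pd.DataFrame({"patient_id": range(n), "a": a, "b": b, "c": c})
        f2 = f1[["patient_id", "c", "b", "a"]]
        m1 = backward_eliminate(f1, surv, ["a", "b", "c"], families=("lognormal",))
        m2 = backward_eliminate(f2, surv, ["c", "b", "a"], families=("lognormal",))
        assert sorted(m1.covariates) == sorted(m2.covariates)

    def test_terminates_within_covariate_count_rounds(self):
        feats, surv = _lognormal_aft_data(200, beta=0.0, seed=5)
        rng = np.random.default_rng(2)
        for name in ("n1", "n2", "n3"):
            feats[name] = rng.normal(size=200)
        m = backward_eliminate(
            feats, surv, ["logKG", "n1", "n2", "n3"], alpha=0.01,
            families=("lognormal",),
        )
        assert len(m.elimination_trace) <= 4


class TestPrediction:
    def test_exponential_closed_form_curves(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(100, 300)
        feats = pd.DataFrame({"patient_id": range(300)})
        m = fit_parametric_survival(
            feats, _surv_frame(t, [1] * 300), covariates=[], families=("exponential",)
        )
        rate = math.exp(-m.coefficients["intercept"])
        grid = np.array([0.0, 50.0, 100.0, 400.0])
        curves = predict_parametric_curves(m, feats.head(3), grid)
        np.testing.assert_allclose(
            curves.to_numpy(), np.tile(np.exp(-rate * grid), (3, 1)), rtol=1e-10
        )

    def test_negative_coefficient_orders_curves(self):
        feats, surv = _lognormal_aft_data(500, beta=-0.5, seed=11)
        m = fit_parametric_survival(feats, surv, families=("lognormal",))
        two = pd.DataFrame({"patient_id": ["lo", "hi"], "logKG": [-1.0, 1.0]})
        curves = predict_parametric_curves(m, two, np.linspace(0, 1500, 40))
        assert (curves.loc["hi"].to_numpy()[1:] < curves.loc["lo"].to_numpy()[1:]).all()

    def test_curves_valid_probabilities(self):
        feats, surv = _lognormal_aft_data(300, seed=13)
        for fam in AFT_FAMILIES:
            m = fit_parametric_survival(feats, surv, families=(fam,))
            curves = predict_parametric_curves(
                m, feats.head(5), np.arange(0, 2001, 5.0)
            ).to_numpy()
            assert curves.min() >= 0 and curves.max() <= 1
            assert np.allclose(curves[:, 0], 1.0)
            assert (np.diff(curves, axis=1) <= 1e-12).all()

    def test_missing_retained_feature_named(self):
        feats, surv = _lognormal_aft_data(200, seed=1)
        m = fit_parametric_survival(feats, surv, families=("lognormal",))
        with pytest.raises(KeyError, match="logKG"):
            predict_parametric_curves(
                m, pd.DataFrame({"patient_id": [1], "other": [0.5]}), [0, 10]
            )
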