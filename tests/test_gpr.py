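"""GP burned-area models: selection, CV, scenario prediction, attribution."""
import numpy as np
import pandas as pd
import pytest

from fireattr.gpr import (
    BurnedAreaGP,
    acc_contribution,
    detrend_experiment,
    driver_exclusion_experiment,
    select_predictors,
)


def _years(n=29):
    return pd.Index(np.arange(1992, 1992 + n), name="year")


def _design(seed=0, n=29):
    rng = np.random.default_rng(seed)
    idx = _years(n)
    return pd.DataFrame({
        "x1": rng.normal(0, 1, n),
        "x2": rng.normal(0, 1, n),
        "x3": rng.normal(0, 1, n),
    }, index=idx)


class TestSelectPredictors:
    def test_noise_free_single_driver_selected_minimal(self):
        X = _design(1)
        y = 2.0 * X["x1"] + 10.0
        sel = select_predictors(X, y, k=5, seed=0)
        assert sel.selected == ("x1",)

    def test_all_subsets_scored(self):
        X = _design(2)
        y = X["x1"] + np.random.default_rng(0).normal(0, 0.1, len(X))
        sel = select_predictors(X, y, k=3)
        assert len(sel.table) == 2 ** 3 - 1

    def test_subset_cap(self):
        X = _design(3)
        sel = select_predictors(X, X["x1"], max_subset_size=1, k=3)
        assert (sel.table["size"] == 1).all()

    def test_too_many_candidates_refused(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 21)),
                         columns=[f"c{i}" for i in range(21)])
        with pytest.raises(ValueError, match="exhaustive"):
            select_predictors(X, X["c0"])

    def test_informative_pair_beats_noise(self):
        hits = 0
        n_trials = 10
        for seed in range(n_trials):
            X = _design(seed + 50)
            rng = np.random.default_rng(seed)
            y = X["x1"] + X["x2"] + rng.normal(0, 0.2, len(X))
            sel = select_predictors(X, y, k=5, seed=seed)
            hits += set(sel.selected) >= {"x1", "x2"} and "x3" not in sel.selected
        assert hits >= 0.8 * n_trials


class TestFitAndPredict:
    def test_noiseless_linear_high_cv_r2(self):
        X = _design(4)[["x1"]]
        y = 2.0 * X["x1"] + 5.0
        res = BurnedAreaGP(y, X).fit(seed=0)
        assert res.cv_r2 >= 0.99

    def test_interpolation_property_at_low_noise(self):
        X = _design(5)[["x1", "x2"]]
        y = 3 * X["x1"] - X["x2"] + 20
        res = BurnedAreaGP(y, X).fit(seed=0)
        assert np.allclose(res.predict(X, clip=False), y, atol=0.3)

    def test_prediction_reverts_toward_mean_off_support(self):
        # a wiggly target keeps the length scale finite, so far outside the
        # training range the posterior mean falls back toward the prior mean
        X = _design(6)[["x1"]]
        rng = np.random.default_rng(6)
        y = pd.Series(100 + 30 * np.sin(3 * X["x1"].to_numpy())
                      + rng.normal(0, 2, len(X)), index=X.index)
        res = BurnedAreaGP(y, X, kernel="rbf").fit(seed=0)
        far = pd.DataFrame({"x1": [25.0]})
        pred = res.predict(far, clip=False)[0]
        assert abs(pred - y.mean()) < abs(y.max() - y.mean())

    def test_missing_predictor_named_in_error(self):
        X = _design(7)[["x1", "x2"]]
        res = BurnedAreaGP(X["x1"] * 2, X).fit(seed=0, n_restarts=1)
        with pytest.raises(KeyError, match="x2"):
            res.predict(pd.DataFrame({"x1": [0.0]}))

    def test_negative_predictions_clipped_and_counted(self):
        X = _design(8)[["x1"]]
        y = pd.Series(np.clip(5 * X["x1"], 0, None), index=X.index)
        res = BurnedAreaGP(y, X, kernel="linear").fit(seed=0, n_restarts=1)
        low = pd.DataFrame({"x1": [-30.0]})
        assert res.predict(low)[0] == 0.0
        assert res.n_clipped_ >= 1

    def test_fold_seed_stability_random_folds(self):
        X = _design(9)[["x1", "x2"]]
        rng = np.random.default_rng(9)
        y = 2 * X["x1"] + X["x2"] + rng.normal(0, 0.3, len(X)) + 10
        r2s = [BurnedAreaGP(y, X).fit(seed=s, n_restarts=1, cv_scheme="random").cv_r2
               for s in range(6)]
        assert np.ptp(r2s) < 0.15

    def test_log_target_round_trip(self):
        X = _design(10)[["x1"]]
        y = pd.Series(np.exp(1.2 + 0.8 * X["x1"].to_numpy()), index=X.index)
        res = BurnedAreaGP(y, X, log_target=True).fit(seed=0)
        assert res.cv_r2 > 0.9


class TestAccContribution:
    def test_identical_scenarios_zero(self):
        p = pd.Series([5.0, 6.0, 7.0])
        assert acc_contribution(p, p).fraction_pct == 0.0

    def test_proportional_case(self):
        obs = pd.Series([10.0, 20.0, 30.0])
        nat = pd.Series([5.0, 10.0, 15.0])
        assert acc_contribution(obs, nat).fraction_pct == pytest.approx(50.0)

    def test_signed_annual_differences_kept(self):
        obs = pd.Series([10.0, 20.0])
        nat = pd.Series([12.0, 8.0])
        c = acc_contribution(obs, nat)
        assert c.fraction_pct == pytest.approx(100 * 10 / 30)
        assert c.annual_difference.iloc[0] == pytest.approx(-2.0)

    def test_zero_observed_total_flagged(self):
        z = pd.Series([0.0, 0.0])
        c = acc_contribution(z, z)
        assert c.undefined and np.isnan(c.fraction_pct)


class TestShap:
    def test_single_predictor_gets_everything(self):
        X = _design(11)[["x1"]]
        res = BurnedAreaGP(2 * X["x1"] + 3, X).fit(seed=0, n_restarts=1)
        imp = res.shap_importance()
        assert imp["x1"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        X = _design(12)
        rng = np.random.default_rng(12)
        y = X["x1"] + 0.5 * X["x2"] + rng.normal(0, 0.2, len(X))
        imp = BurnedAreaGP(y, X).fit(seed=0, n_restarts=1).shap_importance()
        assert imp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_symmetric_design_splits_evenly(self):
        pcts = []
        for seed in range(8):
            X = _design(seed + 200)[["x1", "x2"]]
            y = X["x1"] + X["x2"]
            imp = BurnedAreaGP(y, X).fit(seed=seed, n_restarts=1).shap_importance()
            pcts.append(imp["x1"])
        assert np.mean(pcts) == pytest.approx(50.0, abs=5.0)

    def test_constant_predictor_zero_importance(self):
        X = _design(13)[["x1"]].assign(flat=1.0)
        y = 2 * X["x1"]
        imp = BurnedAreaGP(y, X).fit(seed=0, n_restarts=1).shap_importance()
        assert imp["flat"] == 0.0
        assert imp["x1"] == pytest.approx(100.0)


class TestDriverExclusion:
    def _fit_linear(self, seed=0):
        X = _design(seed)[["x1", "x2"]]
        y = pd.Series(50 + 4 * X["x1"] + 2 * X["x2"], index=X.index)
        res = BurnedAreaGP(y, X, kernel="linear").fit(seed=seed, n_restarts=1)
        return res, X

    def test_zero_signal_zero_contribution(self):
        res, X = self._fit_linear()
        sig = {"x1": pd.Series(0.0, index=X.index)}
        out = driver_exclusion_experiment(res, X, sig)
        row = out[out.driver == "x1"].iloc[0]
        assert row.contribution_pct == pytest.approx(0.0, abs=1e-9)

    def test_linear_model_additivity(self):
        res, X = self._fit_linear(1)
        sig = {"x1": pd.Series(0.4, index=X.index),
               "x2": pd.Series(-0.2, index=X.index)}
        out = driver_exclusion_experiment(res, X, sig).set_index("driver")
        gap = out.loc["__additivity_gap__", "contribution_pct"]
        assert abs(gap) < 1e-6

    def test_nonlinear_gap_reported(self):
        X = _design(2)[["x1", "x2"]]
        y = pd.Series(50 + 4 * X["x1"] ** 2 + 2 * X["x2"], index=X.index)
        res = BurnedAreaGP(y, X, kernel="rbf").fit(seed=0, n_restarts=1)
        sig = {"x1": pd.Series(0.5, index=X.index),
               "x2": pd.Series(0.5, index=X.index)}
        out = driver_exclusion_experiment(res, X, sig).set_index("driver")
        assert "__additivity_gap__" in out.index


class TestDetrend:
    def test_detrended_series_have_zero_slope(self):
        X = _design(3)[["x1"]]
        t = np.arange(len(X), dtype=float)
        X = X.assign(x1=X["x1"] + 0.3 * t)
        y = pd.Series(5 * X["x1"].to_numpy() + 1.5 * t, index=X.index)
        out = detrend_experiment(X, y, select=False, candidates=["x1"], seed=0)
        assert "cv_r2_detrended" in out
        # internal detrending: refit a line to the detrended target, slope ~ 0
        yd = y.to_numpy() - np.polyval(np.polyfit(t, y, 1), t)
        assert abs(np.polyfit(t, yd, 1)[0]) < 1e-9

    def test_trendless_data_unaffected(self):
        deltas = []
        for seed in range(5):
            X = _design(seed + 300)[["x1"]]
            rng = np.random.default_rng(seed)
            y = pd.Series(4 * X["x1"] + rng.normal(0, 0.3, len(X)) + 30, index=X.index)
            out = detrend_experiment(X, y, select=False, candidates=["x1"], seed=seed)
            deltas.append(out["cv_r2_detrended"] - out["cv_r2_original"])
        assert abs(np.mean(deltas)) < 0.1

    def test_pure_trend_target_loses_skill(self):
        X = _design(4)[["x1"]]  # stationary predictor
        t = np.arange(len(X), dtype=float)
        rng = np.random.default_rng(12345)  # independent of the predictor draw
        y = pd.Series(3.0 * t + 100 + rng.normal(0, 0.5, len(X)), index=X.index)
        out = detrend_experiment(X, y, select=False, candidates=["x1"], seed=0)
        r2d = out["cv_r2_detrended"]
        # skill collapses: tiny, or undefined when predictions go constant
        assert np.isnan(r2d) or r2d < 0.3


class TestPartialDependence:
    def test_constant_model_flat_curve(self):
        X = _design(5)[["x1"]]
        y = pd.Series(7.0, index=X.index)
        res = BurnedAreaGP(y, X).fit(seed=0, n_restarts=1)
        curve = res.partial_dependence("x1", grid_points=11)
        assert np.allclose(curve, curve.iloc[0], atol=1e-6)

    def test_linear_response_recovers_slope(self):
        X = _design(6)[["x1"]]
        beta = 4.0
        y = pd.Series(beta * X["x1"] + 10, index=X.index)
        res = BurnedAreaGP(y, X, kernel="linear").fit(seed=0, n_restarts=2)
        curve = res.partial_dependence("x1", grid_points=21)
        slope = np.polyfit(curve.index.to_numpy(), curve.to_numpy(), 1)[0]
        assert slope == pytest.approx(beta, abs=1e-3)

    def test_curve_length(self):
        X = _design(7)[["x1"]]
        res = BurnedAreaGP(2 * X["x1"], X).fit(seed=0, n_restarts=1)
        assert len(res.partial_dependence("x1", grid_points=17)) == 17


def test_summary_mentions_predictors_and_skill():
    X = _design(8)[["x1", "x2"]]
    y = 2 * X["x1"] + X["x2"] + 5
    res = BurnedAreaGP(y, X, name="toy/lightning").fit(seed=0, n_restarts=1)
    text = res.summary()
    assert "toy/lightning" in text and "x1" in text and "R^2" in text
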