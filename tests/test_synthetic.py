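"""Generator contracts: reproducibility, conservation, retrievable truth."""
import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from fireattr import synthetic
from fireattr.synthetic import (
    ResponseSpec,
    SyntheticTruth,
    VariableSpec,
    gen_burned_area_records,
    gen_climate_ensemble,
    gen_concentration_fields,
    gen_emissions_inputs,
    gen_observed_series,
    true_acc_fraction,
)


def _quiet_truth(**kw):
    base = dict(master_seed=3)
    base.update(kw)
    return SyntheticTruth(**base)


def _zero_noise_variables(forced=0.02):
    return {
        "Tmax": VariableSpec(25.0, forced, 0.0, "degC"),
        "VPD": VariableSpec(1.2, forced / 10, 0.0, "kPa", bounds=(0.0, None)),
        "NDVI": VariableSpec(0.45, 0.0, 0.0, "1", bounds=(0.0, 1.0)),
    }


class TestClimateEnsemble:
    def test_degenerate_truth_gives_constant_members(self):
        truth = _quiet_truth(variables={"Tmax": VariableSpec(25.0, 0.0, 0.0, "degC")},
                             model_bias_sd=0.0)
        members = gen_climate_ensemble(truth, n_models=3)["Tmax"]
        for m in members:
            assert np.allclose(m.values, 25.0)

    def test_reproducible_under_same_seed(self):
        truth = _quiet_truth()
        a = gen_climate_ensemble(truth, n_models=4)
        b = gen_climate_ensemble(truth, n_models=4)
        for var in a:
            for ma, mb in zip(a[var], b[var]):
                assert ma.values.equals(mb.values)

    def test_short_year_range_rejected(self):
        with pytest.raises(ValueError, match="year range"):
            gen_climate_ensemble(_quiet_truth(), n_models=3, years=np.arange(1990, 2000))

    def test_member_slopes_recover_generating_trend(self):
        # linear truth so every member's OLS slope estimates the forced slope
        slope, noise = 0.05, 0.3
        errs = []
        for seed in range(25):
            truth = _quiet_truth(
                master_seed=seed, trend_shape="linear",
                variables={"Tmax": VariableSpec(10.0, slope, noise, "degC")},
                model_bias_sd=0.5,
            )
            members = gen_climate_ensemble(truth, n_models=12)["Tmax"]
            years = members[0].values.index.to_numpy(dtype=float)
            fits = [np.polyfit(years, m.values.to_numpy(), 1)[0] for m in members]
            errs.append(np.mean(fits) - slope)
        se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 2 * se + 1e-4


class TestObservedSeries:
    def test_zero_noise_equals_forced_plus_baseline(self):
        truth = _quiet_truth(variables=_zero_noise_variables())
        years = np.arange(1992, 2021)
        obs = gen_observed_series(truth, years)
        for eco in truth.ecoregions:
            expect = 25.0 + truth.forced_component("Tmax", years)
            assert np.allclose(obs.loc[eco, "Tmax"], expect)

    def test_residual_after_removing_forced_is_trendless(self):
        slopes = []
        years = np.arange(1992, 2021)
        for seed in range(30):
            truth = _quiet_truth(master_seed=seed)
            obs = gen_observed_series(truth, years)
            resid = obs.loc[truth.ecoregions[0], "Tmax"].to_numpy() - \
                truth.forced_component("Tmax", years)
            slopes.append(np.polyfit(years, resid, 1)[0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 2 * se + 1e-5

    def test_bounded_variables_respect_bounds(self, truth, observed):
        assert (observed["RHmin"] >= 0).all() and (observed["RHmin"] <= 100).all()
        assert (observed["NDVI"] >= 0).all() and (observed["NDVI"] <= 1).all()
        assert (observed["PRECIP"] >= 0).all()


class TestBurnedAreaRecords:
    def test_identity_response_reproduces_series(self):
        # response = 1 km^2 per kPa of VPD, no noise, no missing causes
        vpd = VariableSpec(0.0, 0.0, 0.0, "kPa")
        truth = _quiet_truth(
            variables={"VPD": vpd},
            response_spec={("NW_Forested_Mts", "lightning"): ResponseSpec(
                predictors=("VPD",), beta=(1.0,), intercept=0.0, noise_sd=0.0)},
            missing_cause_fraction=0.0,
        )
        years = np.arange(2000, 2003)
        obs = pd.DataFrame(
            {"VPD": [1.0, 2.0, 3.0]},
            index=pd.MultiIndex.from_product(
                [["NW_Forested_Mts"], years], names=["ecoregion", "year"]),
        )
        _, table = gen_burned_area_records(truth, obs)
        assert np.allclose(table.sort_values("year")["ba_km2"], [1.0, 2.0, 3.0])

    def test_record_areas_sum_to_annual_table(self, truth, observed):
        records, table = gen_burned_area_records(truth, observed)
        labelled = records[records.cause != "Missing"]
        labelled = labelled.assign(year=pd.to_datetime(labelled.discovery_date).dt.year)
        source = labelled.cause.map({"Natural": "lightning", "Human": "human"})
        sums = labelled.groupby([source, "year"])["area_km2"].sum()
        table_sums = table.groupby(["source", "year"])["ba_km2"].sum()
        for key, expected in table_sums.items():
            assert sums.get(key, 0.0) == pytest.approx(expected, rel=1e-9)

    def test_missing_cause_fraction_within_binomial_ci(self, truth, observed):
        records, _ = gen_burned_area_records(truth, observed)
        n = len(records)
        k = int((records.cause == "Missing").sum())
        p = truth.missing_cause_fraction
        # 99% CI around the target count
        se = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 2.58 * se + 1  # +1 absorbs rounding of the count

    def test_regenerating_records_does_not_change_climate(self, truth, analysis_years):
        obs1 = gen_observed_series(truth, analysis_years)
        gen_burned_area_records(truth, obs1)
        obs2 = gen_observed_series(truth, analysis_years)
        pd.testing.assert_frame_equal(obs1, obs2)


class TestEmissionsInputs:
    def test_noiseless_dm_is_linear_in_ba(self):
        truth = _quiet_truth(dm_ba_slope=2.0, dm_ba_intercept=0.0, dm_noise_frac=0.0)
        ba = pd.DataFrame({
            "ecoregion": ["NW_Forested_Mts"], "source": ["lightning"],
            "year": [2000], "ba_km2": [10.0]})
        dm, _, _ = gen_emissions_inputs(truth, ba)
        assert float(dm.sel(year=2000).sum()) == pytest.approx(20.0, rel=1e-9)

    def test_noiseless_round_trip_recovers_slope(self):
        from fireattr.emissions import fit_dm_ba_relation

        truth = _quiet_truth(dm_noise_frac=0.0)
        years = np.arange(2000, 2012)
        rng = np.random.default_rng(5)
        ba = pd.DataFrame({
            "ecoregion": "NW_Forested_Mts", "source": "lightning",
            "year": years, "ba_km2": rng.uniform(5, 50, len(years))})
        dm, _, _ = gen_emissions_inputs(truth, ba)
        mask = truth.ecoregion_mask().values == 1
        dm_eco = dm.values[:, mask].sum(axis=1)
        rel = fit_dm_ba_relation(dm_eco, ba.ba_km2.to_numpy())
        assert rel.slope == pytest.approx(truth.dm_ba_slope, rel=1e-6)
        assert rel.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_fit_usually_strong(self):
        from fireattr.emissions import fit_dm_ba_relation

        ok = 0
        n_trials = 40
        for seed in range(n_trials):
            truth = _quiet_truth(master_seed=seed, dm_noise_frac=0.1)
            years = np.arange(2000, 2020)
            rng = np.random.default_rng(seed)
            ba = pd.DataFrame({
                "ecoregion": "NW_Forested_Mts", "source": "lightning",
                "year": years, "ba_km2": rng.uniform(5, 50, len(years))})
            dm, _, _ = gen_emissions_inputs(truth, ba)
            mask = truth.ecoregion_mask().values == 1
            rel = fit_dm_ba_relation(dm.values[:, mask].sum(axis=1), ba.ba_km2)
            ok += rel.r2 > 0.6
        assert ok >= 0.9 * n_trials


class TestConcentrationFields:
    def _em(self, truth, values):
        lat, lon = truth.grid_coords()
        import xarray as xr
        return xr.DataArray(values, coords={"year": [2000], "lat": lat, "lon": lon},
                            dims=("year", "lat", "lon"))

    def test_zero_emissions_collapse_experiments(self, truth):
        zeros = self._em(truth, np.zeros((1,) + truth.grid_shape))
        conc = gen_concentration_fields(zeros, zeros, truth)
        assert np.allclose(conc["CTL"], conc["BKG"])
        assert np.allclose(conc["NAT"], conc["BKG"])

    def test_doubling_emissions_doubles_smoke(self, truth):
        rng = np.random.default_rng(1)
        em = self._em(truth, rng.uniform(0, 1e6, (1,) + truth.grid_shape))
        c1 = gen_concentration_fields(em, em, truth)
        c2 = gen_concentration_fields(2 * em, 2 * em, truth)
        smoke1 = c1["CTL"] - c1["BKG"]
        smoke2 = c2["CTL"] - c2["BKG"]
        assert np.allclose(smoke2, 2 * smoke1)

    def test_point_source_peaks_at_source_cell(self, truth):
        values = np.zeros((1,) + truth.grid_shape)
        values[0, 10, 10] = 1e9
        em = self._em(truth, values)
        conc = gen_concentration_fields(em, em, truth)
        smoke = (conc["CTL"] - conc["BKG"]).values[0]
        assert np.unravel_index(np.argmax(smoke), smoke.shape) == (10, 10)


class TestTruthOracle:
    def test_zero_forced_trend_gives_zero_fraction(self, analysis_years):
        truth = _quiet_truth(variables={
            "Tmax": VariableSpec(25.0, 0.0, 0.5, "degC"),
            "VPD": VariableSpec(1.2, 0.0, 0.05, "kPa", bounds=(0.0, None)),
            "NDVI": VariableSpec(0.45, 0.0, 0.03, "1", bounds=(0.0, 1.0)),
        })
        obs = gen_observed_series(truth, analysis_years)
        frac = true_acc_fraction(truth, obs, analysis_years)
        assert np.allclose(frac["acc_fraction_pct"], 0.0)

    def test_pure_forced_response_gives_full_fraction(self, analysis_years):
        # response on a noise-free variable whose entire signal is forced
        truth = _quiet_truth(
            variables={"Tmax": VariableSpec(25.0, 0.02, 0.0, "degC")},
            response_spec={("NW_Forested_Mts", "lightning"): ResponseSpec(
                predictors=("Tmax",), beta=(10.0,), centers=(25.0,),
                intercept=0.0, noise_sd=0.0)},
        )
        obs = gen_observed_series(truth, analysis_years)
        frac = true_acc_fraction(truth, obs, analysis_years)
        assert frac["acc_fraction_pct"].iloc[0] == pytest.approx(100.0)

    def test_linear_response_matches_direct_evaluation(self, truth, observed,
                                                       analysis_years):
        frac = true_acc_fraction(truth, observed, analysis_years)
        eco, src = "Cold_Deserts", "lightning"
        resp = truth.response_spec[(eco, src)]
        X = observed.loc[eco].loc[analysis_years]
        Xcf = X.copy()
        for var in ("Tmax", "VPD"):
            Xcf[var] = X[var] - truth.forced_component(var, analysis_years)
        full = resp.deterministic(X).sum()
        cf = resp.deterministic(Xcf).sum()
        assert frac.loc[(eco, src), "acc_fraction_pct"] == pytest.approx(
            100 * (full - cf) / full)

    def test_oracle_invariant_to_noise_seed(self, analysis_years):
        t1 = _quiet_truth(master_seed=11)
        obs = gen_observed_series(t1, analysis_years)
        f1 = true_acc_fraction(t1, obs, analysis_years)
        f2 = true_acc_fraction(replace(t1, master_seed=12), obs, analysis_years)
        pd.testing.assert_frame_equal(f1, f2)


def test_invalid_truth_rejected():
    with pytest.raises(ValueError):
        SyntheticTruth(missing_cause_fraction=1.5)
    with pytest.raises(ValueError):
        VariableSpec(0.0, 0.0, -1.0, "K")
    with pytest.raises(ValueError):
        SyntheticTruth(emission_factors={"forest": {"OC": -1.0}})
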