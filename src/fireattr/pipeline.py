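"""End-to-end attribution pipeline on synthetic inputs.

Stages (each reads the previous stage's files from the run directory, so
they can also be invoked standalone through the CLI):

1. ``simulate``      — generate all inputs with known truth
2. ``fire-records``  — filter + stratify records into annual burned area
3. ``acc-signal``    — forced-signal extraction from the pseudo-ensemble
4. ``attribute-ba``  — natural scenario, GP fits, scenario predictions, ACC fractions
5. ``emissions``     — dry-matter scaling and species emissions per scenario
6. ``smoke``         — concentration differencing, exposure, trend attribution
7. ``report``        — machine-readable manifest with headline numbers

Everything stochastic flows from ``RunConfig.master_seed``; two runs with the
same config produce identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import climate, emissions, fire_records, gpr, smoke, synthetic
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "build_truth", "run_full_attribution"]

STAGES = ("simulate", "fire-records", "acc-signal", "attribute-ba",
          "emissions", "smoke", "report")


@dataclass
class RunConfig:
    """Configuration of a full attribution run (YAML round-trippable)."""

    outdir: str = "runs/default"
    master_seed: int = 0
    analysis_years: tuple = (1992, 2020)
    ensemble_years: tuple = (1920, 2020)
    n_models: int = 12
    window: int = 20
    reference: tuple = (1921, 1940)
    candidates: tuple = ("Tmax", "VPD", "PRECIP", "NDVI")
    select: bool = True
    max_subset_size: int = 3
    k_folds: int = 5
    cv_scheme: str = "blocked"
    kernel: str = "rbf+linear"
    log_target: bool = False
    n_restarts: int = 2
    periods: tuple = ((1992, 2005), (2006, 2020))
    ratio_cap: float = 5.0
    r2_method: str = "pearson"
    run_driver_exclusion: bool = True
    run_shap: bool = True
    run_detrend: bool = False
    fire_season_mode: bool = False  # with annual synthetic inputs this is a no-op
    realization_mean_mode: bool = False  # single-realization default
    truth_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("analysis_years", "ensemble_years", "reference",
                     "candidates", "periods"):
            v = getattr(self, name)
            if isinstance(v, list):
                setattr(self, name, tuple(tuple(x) if isinstance(x, list) else x for x in v))

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def run_dir(self) -> Path:
        return Path(self.outdir)


def build_truth(cfg: RunConfig) -> SyntheticTruth:
    """Synthetic truth implied by a config (same config => same truth)."""
    kwargs = dict(
        master_seed=cfg.master_seed,
        analysis_years=tuple(cfg.analysis_years),
        ensemble_years=tuple(cfg.ensemble_years),
    )
    kwargs.update(cfg.truth_overrides)
    return SyntheticTruth(**kwargs)


def _years(cfg: RunConfig) -> np.ndarray:
    return np.arange(cfg.analysis_years[0], cfg.analysis_years[1] + 1)


def _write_nc(da: xr.DataArray, path: Path) -> None:
    da.to_netcdf(path, engine="scipy")


def _read_nc(path: Path) -> xr.DataArray:
    with xr.open_dataarray(path, engine="scipy") as da:
        return da.load()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> dict:
    truth = build_truth(cfg)
    d = cfg.run_dir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    years = _years(cfg)

    ensemble = synthetic.gen_climate_ensemble(truth, n_models=cfg.n_models)
    rows = []
    for var, members in ensemble.items():
        for m in members:
            for y, v in m.values.items():
                rows.append((var, m.model_id, int(y), float(v)))
    pd.DataFrame(rows, columns=["variable", "model_id", "year", "value"]).to_csv(
        d / "ensemble.csv", index=False)

    observed = synthetic.gen_observed_series(truth, years)
    observed.to_csv(d / "observed_climate.csv")

    records, truth_table = synthetic.gen_burned_area_records(truth, observed)
    records.to_csv(d / "fire_records.csv", index=False)
    truth_table.to_csv(d / "truth_ba_table.csv", index=False)

    fractions = synthetic.true_acc_fraction(truth, observed, years)
    fractions.to_csv(d / "truth_acc_fractions.csv")

    dm, type_fractions, ef_table = synthetic.gen_emissions_inputs(truth, truth_table)
    _write_nc(dm, d / "dm_observed.nc")
    for name, frac in type_fractions.items():
        _write_nc(frac.rename(f"fraction_{name}"), d / f"type_fraction_{name}.nc")
    (d / "ef_table.json").write_text(json.dumps(ef_table, indent=2))
    _write_nc(truth.ecoregion_mask(), d / "ecoregion_mask.nc")
    _write_nc(truth.population(), d / "population.nc")
    (d / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    return {"n_records": len(records), "n_models": cfg.n_models,
            "truth_acc_fractions": {f"{e}/{s}": v for (e, s), v in
                                    fractions["acc_fraction_pct"].items()}}


def stage_fire_records(cfg: RunConfig) -> dict:
    truth = build_truth(cfg)
    d = cfg.run_dir
    records_path = d / "inputs" / "fire_records.csv"
    parsed, report = fire_records.parse_and_filter_records(
        records_path, tuple(cfg.analysis_years))
    mask = _read_nc(d / "inputs" / "ecoregion_mask.nc")
    strat = fire_records.stratify_annual_ba(
        parsed, mask, tuple(cfg.analysis_years), ecoregion_names=truth.ecoregions)
    out = d / "fire_records_stage"
    out.mkdir(parents=True, exist_ok=True)
    strat.table.to_csv(out / "stratified_ba.csv", index=False)
    _write_nc(strat.gridded, out / "gridded_ba.nc")
    (out / "exclusion_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    from .trends import theil_sen_trend

    trend_rows = []
    for (eco, src), grp in strat.table.groupby(["ecoregion", "source"]):
        series = grp.set_index("year")["ba_km2"].sort_index()
        if len(series) < 3:
            continue
        t = theil_sen_trend(series)
        trend_rows.append({"ecoregion": eco, "source": src, "slope_km2_per_yr": t.slope,
                           "slope_sigma_per_decade": t.slope_sigma_per_decade,
                           "mk_s": t.mk_s, "p_value": t.p_value,
                           "significant": t.significant})
    pd.DataFrame(trend_rows).to_csv(out / "ba_trends.csv", index=False)
    return {"exclusions": report.as_dict(), "n_strata": strat.table[["ecoregion", "source"]]
            .drop_duplicates().shape[0]}


def _load_members(path: Path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for (var, mid), grp in df.groupby(["variable", "model_id"]):
        series = grp.set_index("year")["value"].sort_index()
        out.setdefault(var, []).append(
            climate.EnsembleMemberSeries(model_id=mid, variable=var, values=series))
    return out


def stage_acc_signal(cfg: RunConfig) -> dict:
    d = cfg.run_dir
    members = _load_members(d / "inputs" / "ensemble.csv")
    years = _years(cfg)
    out = d / "acc_signal_stage"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    trend_info = {}
    for var, mem in members.items():
        sig = climate.acc_signal_from_ensemble(
            mem, window=cfg.window, reference=tuple(cfg.reference), target_years=years)
        for y, v in sig.signal.items():
            rows.append((var, int(y), float(v)))
        trend_info[var] = {
            "slope_per_yr": sig.trend.slope if sig.trend else None,
            "significant": bool(sig.trend.significant) if sig.trend else None,
            "end_of_period_signal": float(sig.signal.iloc[-1]),
            "n_models": sig.n_models,
        }
    pd.DataFrame(rows, columns=["variable", "year", "signal"]).to_csv(
        out / "acc_signals.csv", index=False)
    (out / "signal_trends.json").write_text(json.dumps(trend_info, indent=2))
    return {"signals": trend_info}


def _load_signals(path: Path) -> dict:
    df = pd.read_csv(path)
    return {var: grp.set_index("year")["signal"].sort_index()
            for var, grp in df.groupby("variable")}


def stage_attribute_ba(cfg: RunConfig) -> dict:
    truth = build_truth(cfg)
    d = cfg.run_dir
    observed = pd.read_csv(d / "inputs" / "observed_climate.csv",
                           index_col=["ecoregion", "year"])
    signals = _load_signals(d / "acc_signal_stage" / "acc_signals.csv")
    strat = pd.read_csv(d / "fire_records_stage" / "stratified_ba.csv")
    natural = climate.build_natural_scenario(observed, signals)
    out = d / "attribute_ba_stage"
    out.mkdir(parents=True, exist_ok=True)
    natural.data.to_csv(out / "natural_climate.csv")

    years = _years(cfg)
    pred_rows, attr_rows, sel_rows, driver_rows = [], [], [], []
    for (eco, src), grp in strat.groupby(["ecoregion", "source"]):
        y = grp.set_index("year")["ba_km2"].reindex(years, fill_value=0.0)
        X_obs = observed.loc[eco].loc[years]
        X_nat = natural.data.loc[eco].loc[years]
        candidates = [c for c in cfg.candidates if c in X_obs.columns]
        if cfg.select:
            sel = gpr.select_predictors(
                X_obs, y, candidates=candidates, max_subset_size=cfg.max_subset_size,
                k=cfg.k_folds, seed=cfg.master_seed, kernel=cfg.kernel,
                cv_scheme=cfg.cv_scheme, log_target=cfg.log_target)
            predictors = list(sel.selected)
            for _, r in sel.table.iterrows():
                sel_rows.append({"ecoregion": eco, "source": src,
                                 "subset": "+".join(r["subset"]), "cv_r2": r["cv_r2"]})
        else:
            predictors = candidates
        model = gpr.BurnedAreaGP(y, X_obs[predictors], name=f"{eco}/{src}",
                                 kernel=cfg.kernel, log_target=cfg.log_target)
        res = model.fit(seed=cfg.master_seed, n_restarts=cfg.n_restarts,
                        cv=cfg.k_folds, cv_scheme=cfg.cv_scheme)
        pred_obs = res.predict(X_obs)
        pred_nat = res.predict(X_nat)
        contrib = gpr.acc_contribution(pred_obs, pred_nat)
        skill = fire_records.skill_metrics(pred_obs.to_numpy(), y.to_numpy(),
                                           r2_method=cfg.r2_method)
        row = {
            "ecoregion": eco, "source": src,
            "predictors": "+".join(predictors),
            "acc_fraction_pct": contrib.fraction_pct,
            "pred_total_obs_km2": contrib.total_obs,
            "pred_total_nat_km2": contrib.total_nat,
            "nat_over_recorded_pct": 100.0 * contrib.total_nat / y.sum() if y.sum() else np.nan,
            "cv_r2": res.cv_r2, "cv_rmse": res.cv_rmse,
            "r2_vs_obs": skill.r2, "nmb_pct": skill.nmb_pct,
            "extreme_year_nmb_pct": skill.extreme_year_nmb_pct,
        }
        if cfg.run_shap:
            imp = res.shap_importance()
            row["shap_importance_pct"] = json.dumps(
                {k: round(float(v), 3) for k, v in imp.items()})
        if cfg.run_detrend:
            det = gpr.detrend_experiment(
                X_obs[predictors], y, candidates=predictors, select=False,
                k=cfg.k_folds, seed=cfg.master_seed, kernel=cfg.kernel)
            row["cv_r2_detrended"] = det["cv_r2_detrended"]
        attr_rows.append(row)
        if cfg.run_driver_exclusion:
            dr = gpr.driver_exclusion_experiment(res, X_obs, signals)
            for _, r in dr.iterrows():
                driver_rows.append({"ecoregion": eco, "source": src, **r.to_dict()})
        for scen, pred in (("observed", pred_obs), ("natural", pred_nat)):
            for yy, v in pred.items():
                pred_rows.append({"ecoregion": eco, "source": src, "year": int(yy),
                                  "scenario": scen, "ba_km2": float(v)})
    pd.DataFrame(pred_rows).to_csv(out / "ba_predictions.csv", index=False)
    attribution = pd.DataFrame(attr_rows)
    attribution.to_csv(out / "attribution.csv", index=False)
    if sel_rows:
        pd.DataFrame(sel_rows).to_csv(out / "selection_tables.csv", index=False)
    if driver_rows:
        pd.DataFrame(driver_rows).to_csv(out / "driver_contributions.csv", index=False)
    return {"attribution": attribution[["ecoregion", "source", "acc_fraction_pct",
                                        "cv_r2"]].to_dict("records")}


def stage_emissions(cfg: RunConfig) -> dict:
    truth = build_truth(cfg)
    d = cfg.run_dir
    dm_obs = _read_nc(d / "inputs" / "dm_observed.nc")
    ef_table = json.loads((d / "inputs" / "ef_table.json").read_text())
    mask = _read_nc(d / "inputs" / "ecoregion_mask.nc")
    type_fractions = {
        name: _read_nc(d / "inputs" / f"type_fraction_{name}.nc")
        for name in ef_table
    }
    preds = pd.read_csv(d / "attribute_ba_stage" / "ba_predictions.csv")
    obs_pred = preds[preds.scenario == "observed"]
    nat_pred = preds[preds.scenario == "natural"]
    ratios = emissions.scenario_dm_ratios(obs_pred, nat_pred, ratio_cap=cfg.ratio_cap)
    natural = emissions.build_natural_emissions(
        dm_obs, ratios, mask, truth.ecoregions, ef_table, type_fractions)
    observed_species = emissions.species_from_dm(dm_obs, ef_table, type_fractions)
    out = d / "emissions_stage"
    out.mkdir(parents=True, exist_ok=True)
    ratios.to_csv(out / "dm_ratios.csv", index=False)
    _write_nc(natural["DM"], out / "dm_natural.nc")
    summary = {}
    for sp in observed_species:
        _write_nc(observed_species[sp], out / f"{sp}_observed.nc")
        _write_nc(natural[sp], out / f"{sp}_natural.nc")
        tot = emissions.species_totals_and_acc_share(observed_species[sp], natural[sp])
        summary[sp] = {
            "cumulative_obs_kg": tot["cumulative_obs"],
            "cumulative_nat_kg": tot["cumulative_nat"],
            "acc_share_pct": tot["acc_share_pct"],
            "acc_trend_share_pct": tot["acc_trend_share_pct"],
            "obs_trend_significant": tot["trend_obs"].significant,
        }
    # diagnostic DM~BA relation per ecoregion
    strat = pd.read_csv(d / "fire_records_stage" / "stratified_ba.csv")
    ba_tot = strat.groupby(["ecoregion", "year"])["ba_km2"].sum()
    dm_eco = {}
    for i, eco in enumerate(truth.ecoregions):
        sel = mask.values == i + 1
        dm_eco[eco] = dm_obs.values[:, sel].sum(axis=1)
    rel_rows = []
    for eco in truth.ecoregions:
        ba = ba_tot.loc[eco].reindex(dm_obs["year"].values, fill_value=0.0)
        try:
            rel = emissions.fit_dm_ba_relation(dm_eco[eco], ba.to_numpy(), eco)
            rel_rows.append({"ecoregion": eco, "slope": rel.slope,
                             "intercept": rel.intercept, "r2": rel.r2})
        except ValueError:
            rel_rows.append({"ecoregion": eco, "slope": np.nan,
                             "intercept": np.nan, "r2": np.nan})
    pd.DataFrame(rel_rows).to_csv(out / "dm_ba_relations.csv", index=False)
    (out / "emissions_summary.json").write_text(json.dumps(summary, indent=2))
    return {"species": summary}


def stage_smoke(cfg: RunConfig) -> dict:
    truth = build_truth(cfg)
    d = cfg.run_dir
    es = d / "emissions_stage"

    def smoke_mass(tag: str) -> xr.DataArray:
        oc = _read_nc(es / f"OC_{tag}.nc")
        bc = _read_nc(es / f"BC_{tag}.nc")
        return smoke.oa_from_oc(oc) + bc

    em_obs = smoke_mass("observed")
    em_nat = smoke_mass("natural")
    conc = synthetic.gen_concentration_fields(em_obs, em_nat, truth)
    fields = smoke.derive_smoke_fields(conc["CTL"], conc["NAT"], conc["BKG"])
    split = smoke.split_acc_nv(fields["smoke_obs"], fields["smoke_nat"])
    out = d / "smoke_stage"
    out.mkdir(parents=True, exist_ok=True)
    for name, f in (("smoke_obs", fields["smoke_obs"]), ("smoke_nat", fields["smoke_nat"]),
                    ("acc", split["acc"]), ("nv", split["nv"])):
        _write_nc(f.rename(name), out / f"{name}.nc")

    maps = smoke.contribution_maps(
        {"smoke": fields["smoke_obs"], "acc": split["acc"], "nv": split["nv"]},
        conc["CTL"], [tuple(p) for p in cfg.periods])
    for (name, period), m in maps.items():
        _write_nc(m.rename(f"pct_{name}"), out / f"pct_{name}_{period[0]}_{period[1]}.nc")

    domain_obs = fields["smoke_obs"].mean(("lat", "lon")).to_series()
    domain_acc = split["acc"].mean(("lat", "lon")).to_series()
    trend = smoke.trend_attribution(domain_obs, domain_acc,
                                    tuple(cfg.periods[-1]))
    acc_share = (100.0 * float(split["acc"].sum()) / float(fields["smoke_obs"].sum())
                 if float(fields["smoke_obs"].sum()) else np.nan)

    population = _read_nc(d / "inputs" / "population.nc")
    mask = _read_nc(d / "inputs" / "ecoregion_mask.nc")
    region_masks = {eco: mask == i + 1 for i, eco in enumerate(truth.ecoregions)}
    exposure = smoke.population_weighted_exposure(
        {"total": fields["smoke_obs"], "acc": split["acc"], "nv": split["nv"]},
        population, region_masks)
    exposure.table.to_csv(out / "exposure.csv")
    summary = {
        "smoke_acc_share_pct": acc_share,
        "mean_smoke_obs_ugm3": float(domain_obs.mean()),
        "mean_smoke_nat_ugm3": float(fields["smoke_nat"].mean()),
        "trend_attribution": {k: (bool(v) if isinstance(v, np.bool_) else
                                  float(v) if isinstance(v, (int, float, np.floating)) else v)
                              for k, v in trend.items()},
        "n_floored": fields["n_floored"],
        "exposure_flags": exposure.flags,
    }
    (out / "smoke_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_report(cfg: RunConfig) -> dict:
    d = cfg.run_dir
    attribution = pd.read_csv(d / "attribute_ba_stage" / "attribution.csv")
    truth_fracs = pd.read_csv(d / "inputs" / "truth_acc_fractions.csv",
                              index_col=["ecoregion", "source"])
    emissions_summary = json.loads((d / "emissions_stage" / "emissions_summary.json").read_text())
    smoke_summary = json.loads((d / "smoke_stage" / "smoke_summary.json").read_text())
    exclusions = json.loads((d / "fire_records_stage" / "exclusion_report.json").read_text())

    per_stratum = []
    for _, r in attribution.iterrows():
        tf = float(truth_fracs.loc[(r.ecoregion, r.source), "acc_fraction_pct"])
        per_stratum.append({
            "ecoregion": r.ecoregion, "source": r.source,
            "acc_fraction_pct": float(r.acc_fraction_pct),
            "true_acc_fraction_pct": tf,
            "error_points": float(r.acc_fraction_pct) - tf,
            "cv_r2": float(r.cv_r2),
        })
    total_obs = attribution["pred_total_obs_km2"].sum()
    total_nat = attribution["pred_total_nat_km2"].sum()
    overall = 100.0 * (total_obs - total_nat) / total_obs if total_obs else np.nan

    manifest = {
        "config": dataclasses.asdict(cfg),
        "headline": {
            "overall_acc_fraction_pct": overall,
            "acc_fraction_by_stratum": per_stratum,
            "oc_emissions_acc_share_pct": emissions_summary.get("OC", {}).get("acc_share_pct"),
            "smoke_acc_share_pct": smoke_summary["smoke_acc_share_pct"],
            "smoke_trend_acc_share_pct": smoke_summary["trend_attribution"].get("acc_trend_share_pct"),
        },
        "exclusions": exclusions,
        "input_hashes": {
            p.name: _hash_file(p) for p in sorted((d / "inputs").glob("*.csv"))
        },
        "output_hashes": {
            "attribution.csv": _hash_file(d / "attribute_ba_stage" / "attribution.csv"),
        },
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fire-records": stage_fire_records,
    "acc-signal": stage_acc_signal,
    "attribute-ba": stage_attribute_ba,
    "emissions": stage_emissions,
    "smoke": stage_smoke,
    "report": stage_report,
}


def run_full_attribution(cfg: RunConfig) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    cfg.run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(cfg.run_dir / "config.yaml")
    manifest = None
    for stage in STAGES:
        logger.info("running stage %s", stage)
        try:
            result = STAGE_FUNCS[stage](cfg)
        except Exception as exc:  # noqa: BLE001 - context for stage failures
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        if stage == "report":
            manifest = result
    return manifest
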