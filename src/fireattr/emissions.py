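"""Fire-emissions algebra: dry matter burned, emission factors, scenario scaling.

Species emissions follow the standard inventory decomposition

    emission(species, cell, year) =
        sum over fire types of  DM(cell, year) * fraction(type, cell) * EF(type, species) / 1000

with DM in kg, EF in g species per kg dry matter, and emissions in kg.
Counterfactual ("natural") emissions keep the observed spatial pattern of
burning and scale each ecoregion-year's dry matter by the ratio of predicted
burned areas natural/observed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .trends import TrendResult, theil_sen_trend

logger = logging.getLogger(__name__)

__all__ = [
    "DMBARelation",
    "fit_dm_ba_relation",
    "scenario_dm_ratios",
    "build_natural_emissions",
    "species_from_dm",
    "species_totals_and_acc_share",
]

#: cap on the natural/observed burned-area ratio for degenerate denominators
DEFAULT_RATIO_CAP = 5.0


@dataclass(frozen=True)
class DMBARelation:
    """OLS relation between annual dry matter burned and burned area."""

    ecoregion: str
    slope: float  # kg dry matter per km2 burned
    intercept: float  # kg
    r2: float
    n_years: int


def fit_dm_ba_relation(annual_dm, annual_ba, ecoregion: str = "") -> DMBARelation:
    """OLS fit of annual dry matter (kg) on annual burned area (km^2).

    Kept as a diagnostic of how tightly fuel consumption tracks burned area;
    the scenario scaling itself uses the pure burned-area ratio.
    """
    dm = np.asarray(annual_dm, dtype=float)
    ba = np.asarray(annual_ba, dtype=float)
    if len(dm) != len(ba) or len(dm) < 5:
        raise ValueError("need >= 5 paired years")
    if np.std(ba) == 0:
        raise ValueError("burned area has zero variance; relation undefined")
    from scipy.stats import linregress

    fit = linregress(ba, dm)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)  # constant DM
    return DMBARelation(ecoregion=ecoregion, slope=float(fit.slope),
                        intercept=float(fit.intercept), r2=r2, n_years=len(dm))


def scenario_dm_ratios(ba_obs_pred: pd.DataFrame, ba_nat_pred: pd.DataFrame,
                       ratio_cap: float = DEFAULT_RATIO_CAP) -> pd.DataFrame:
    """Per (ecoregion, year) ratio natural/observed of predicted burned area.

    Predictions are summed over ignition sources first (inventory dry matter
    is not ignition-stratified). A zero observed prediction with nonzero
    natural prediction is capped at ``ratio_cap`` with a warning.
    """
    def _totals(df: pd.DataFrame) -> pd.Series:
        return df.groupby(["ecoregion", "year"])["ba_km2"].sum()

    obs = _totals(ba_obs_pred)
    nat = _totals(ba_nat_pred)
    idx = obs.index.union(nat.index)
    obs = obs.reindex(idx, fill_value=0.0)
    nat = nat.reindex(idx, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = nat / obs
    degenerate = (obs == 0) & (nat > 0)
    if degenerate.any():
        logger.warning("capping %d degenerate BA ratios at %.1f",
                       int(degenerate.sum()), ratio_cap)
    r = r.where(~degenerate, ratio_cap)
    r = r.fillna(1.0)  # 0/0: no fire predicted either way, keep DM unchanged
    r = r.clip(upper=ratio_cap)
    return r.rename("ratio").reset_index()


def build_natural_emissions(observed_dm: xr.DataArray, ratios: pd.DataFrame,
                            ecoregion_mask: xr.DataArray, ecoregion_names,
                            ef_table: dict, type_fractions: dict) -> dict:
    """Counterfactual DM grid and species emissions under the natural scenario.

    natural DM(cell, y) = observed DM(cell, y) * r(ecoregion(cell), y); the
    observed spatial (and sub-annual, if present) distribution of burning is
    preserved. Returns {"DM": DataArray, species: DataArray, ...} in kg.
    """
    r_lut = ratios.set_index(["ecoregion", "year"])["ratio"]
    scale = xr.ones_like(observed_dm, dtype=float)
    mask_vals = ecoregion_mask.values
    for i, eco in enumerate(ecoregion_names):
        cells = mask_vals == i + 1
        for t, y in enumerate(observed_dm["year"].values):
            r = float(r_lut.get((eco, int(y)), 1.0))
            scale.values[t][cells] = r
    natural_dm = observed_dm * scale
    natural_dm.name = "dry_matter"
    natural_dm.attrs["units"] = "kg"
    out = {"DM": natural_dm}
    out.update(species_from_dm(natural_dm, ef_table, type_fractions))
    return out


def species_from_dm(dm: xr.DataArray, ef_table: dict, type_fractions: dict) -> dict:
    """Species emissions (kg) from a DM grid via fire-type fractions and EFs."""
    species = sorted({s for table in ef_table.values() for s in table})
    missing = [t for t in type_fractions if t not in ef_table]
    if missing:
        raise ValueError(f"no emission factors for fire type(s) {missing}")
    out = {}
    for sp in species:
        total = None
        for ftype, frac in type_fractions.items():
            ef = ef_table[ftype].get(sp, 0.0)
            if ef < 0:
                raise ValueError("emission factors must be >= 0")
            term = dm * frac * (ef / 1000.0)
            total = term if total is None else total + term
        total.name = sp
        total.attrs["units"] = "kg"
        out[sp] = total
    return out


def species_totals_and_acc_share(obs: xr.DataArray, nat: xr.DataArray,
                                 alpha: float = 0.05) -> dict:
    """Annual/cumulative totals per scenario, the ACC share, and the trend split.

    ACC share = 100 * (obs - nat) / obs on cumulative domain totals; the trend
    split is the Theil–Sen slope of the annual ACC component over the slope of
    the observed annual totals.
    """
    if obs.shape != nat.shape:
        raise ValueError("scenario grids are not aligned")
    obs_annual = obs.sum(("lat", "lon")).to_series()
    nat_annual = nat.sum(("lat", "lon")).to_series()
    acc_annual = obs_annual - nat_annual
    cum_obs = float(obs_annual.sum())
    cum_nat = float(nat_annual.sum())
    share = 100.0 * (cum_obs - cum_nat) / cum_obs if cum_obs else float("nan")
    trend_obs = theil_sen_trend(obs_annual, alpha=alpha)
    trend_nat = theil_sen_trend(nat_annual, alpha=alpha)
    trend_acc = theil_sen_trend(acc_annual, alpha=alpha)
    trend_ratio = (100.0 * trend_acc.slope / trend_obs.slope
                   if trend_obs.slope != 0 else float("nan"))
    acc_map = (obs - nat).mean("year")
    return {
        "annual_obs": obs_annual,
        "annual_nat": nat_annual,
        "annual_acc": acc_annual,
        "cumulative_obs": cum_obs,
        "cumulative_nat": cum_nat,
        "acc_share_pct": share,
        "trend_obs": trend_obs,
        "trend_nat": trend_nat,
        "trend_acc": trend_acc,
        "acc_trend_share_pct": trend_ratio,
        "acc_map": acc_map,
    }
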