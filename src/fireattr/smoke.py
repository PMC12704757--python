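"""Smoke PM2.5 decomposition and population-weighted exposure.

Three concentration experiments define the decomposition: CTL (observed fire
emissions), NAT (counterfactual fire emissions) and BKG (no fire emissions),
all with identical non-fire sources and meteorology. Then

    smoke_obs = CTL - BKG        (all fire smoke)
    smoke_nat = NAT - BKG        (smoke under the natural climate)
    ACC       = smoke_obs - smoke_nat
    NV        = smoke_nat

and ACC + NV == smoke_obs exactly. Exposure metrics weight concentrations by
a gridded population within region masks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .trends import theil_sen_trend

logger = logging.getLogger(__name__)

__all__ = [
    "derive_smoke_fields",
    "split_acc_nv",
    "contribution_maps",
    "trend_attribution",
    "population_weighted_exposure",
    "oa_from_oc",
    "OA_OC_RATIO",
]

#: organic aerosol to organic carbon mass ratio
OA_OC_RATIO = 2.1

#: minimum total PM2.5 for percent-contribution maps (ug m-3)
DEFAULT_TOTAL_FLOOR = 0.1


def _check_aligned(*fields: xr.DataArray):
    first = fields[0]
    for f in fields[1:]:
        if f.shape != first.shape or not np.array_equal(f["year"], first["year"]) \
                or not np.array_equal(f["lat"], first["lat"]):
            raise ValueError("concentration fields are not aligned")


def derive_smoke_fields(ctl: xr.DataArray, nat: xr.DataArray,
                        bkg: xr.DataArray, floor_negatives: bool = True) -> dict:
    """Smoke concentrations under the observed and natural scenarios.

    smoke_obs = CTL - BKG; smoke_nat = NAT - BKG. Tiny numerical negatives
    are floored at 0 with a count (``n_floored``).
    """
    _check_aligned(ctl, nat, bkg)
    smoke_obs = ctl - bkg
    smoke_nat = nat - bkg
    n_floored = 0
    if floor_negatives:
        n_floored = int((smoke_obs < 0).sum()) + int((smoke_nat < 0).sum())
        if n_floored:
            logger.info("flooring %d negative smoke values at 0", n_floored)
        smoke_obs = smoke_obs.clip(min=0.0)
        smoke_nat = smoke_nat.clip(min=0.0)
    smoke_obs.name = smoke_nat.name = "smoke_pm25"
    return {"smoke_obs": smoke_obs, "smoke_nat": smoke_nat, "n_floored": n_floored}


def split_acc_nv(smoke_obs: xr.DataArray, smoke_nat: xr.DataArray) -> dict:
    """ACC = smoke_obs - smoke_nat, NV = smoke_nat; ACC + NV == smoke_obs exactly."""
    _check_aligned(smoke_obs, smoke_nat)
    acc = smoke_obs - smoke_nat
    return {"acc": acc, "nv": smoke_nat}


def contribution_maps(components: dict, total: xr.DataArray, periods,
                      total_floor: float = DEFAULT_TOTAL_FLOOR) -> dict:
    """Percent contribution of each smoke component to total PM2.5 per period.

    For each (component, period): 100 * mean(component) / mean(total) per
    cell over the period's years; cells whose mean total falls below
    ``total_floor`` are masked.
    """
    out = {}
    years = total["year"].values
    for period in periods:
        y0, y1 = period
        sel = (years >= y0) & (years <= y1)
        if not sel.any():
            raise ValueError(f"period {period} contains no years")
        tmean = total.isel(year=sel).mean("year")
        denom = tmean.where(tmean >= total_floor)
        for name, comp in components.items():
            cmean = comp.isel(year=sel).mean("year")
            out[(name, period)] = 100.0 * cmean / denom
    return out


def trend_attribution(smoke_obs_series: pd.Series, acc_series: pd.Series,
                      window_years: tuple, alpha: float = 0.05) -> dict:
    """Percent of the smoke trend explained by ACC over a window.

    100 * TheilSen(acc) / TheilSen(smoke_obs) over ``window_years``; flagged
    not-meaningful when the total trend is nonpositive.
    """
    y0, y1 = window_years
    obs = smoke_obs_series.loc[y0:y1]
    acc = acc_series.loc[y0:y1]
    if len(obs) < 5:
        raise ValueError("trend window must contain >= 5 years")
    t_obs = theil_sen_trend(obs, alpha=alpha)
    t_acc = theil_sen_trend(acc, alpha=alpha)
    meaningful = t_obs.slope > 0
    pct = 100.0 * t_acc.slope / t_obs.slope if meaningful else float("nan")
    if not meaningful:
        logger.warning("total smoke trend nonpositive in %s; ratio not meaningful",
                       window_years)
    return {
        "acc_trend_share_pct": pct,
        "slope_total": t_obs.slope,
        "slope_acc": t_acc.slope,
        "total_trend_significant": t_obs.significant,
        "p_value_total": t_obs.p_value,
        "meaningful": meaningful,
    }


@dataclass(frozen=True)
class ExposureTable:
    """Population-weighted concentrations per region and year, split by driver."""

    table: pd.DataFrame  # index (region, year), columns total/acc/nv
    flags: dict


def population_weighted_exposure(fields: dict, population: xr.DataArray,
                                 region_masks: dict) -> ExposureTable:
    """Population-weighted smoke exposure per region and year.

    ``fields`` maps component names (e.g. "total", "acc", "nv") to aligned
    (year, lat, lon) concentration fields; ``region_masks`` maps region names
    to boolean (lat, lon) masks. The region value is sum(c_i p_i)/sum(p_i)
    over the region's cells. Regions with zero population are flagged and
    reported as NaN.
    """
    rows = []
    flags = {}
    some = next(iter(fields.values()))
    years = some["year"].values
    for region, mask in region_masks.items():
        pop = population.where(mask, 0.0)
        ptot = float(pop.sum())
        if ptot == 0:
            flags[region] = "zero_population"
            for y in years:
                for k in fields:
                    rows.append({"region": region, "year": int(y), "component": k,
                                 "value": float("nan")})
            continue
        w = pop / ptot
        for k, f in fields.items():
            vals = (f * w).sum(("lat", "lon")).to_series()
            for y, v in vals.items():
                rows.append({"region": region, "year": int(y), "component": k,
                             "value": float(v)})
    df = (pd.DataFrame(rows)
          .set_index(["region", "year", "component"])["value"]
          .unstack("component"))
    df.columns.name = None
    return ExposureTable(table=df, flags=flags)


def exposure_weight_map(conc: xr.DataArray, population: xr.DataArray) -> xr.DataArray:
    """Map of c_i * (p_i / P_domain): where smoke affects the most people."""
    return conc * (population / float(population.sum()))


def oa_from_oc(oc: xr.DataArray, ratio: float = OA_OC_RATIO) -> xr.DataArray:
    """Organic aerosol from organic carbon, OA = 2.1 * OC elementwise."""
    oc_vals = np.asarray(oc)
    if (oc_vals < 0).any():
        raise ValueError("OC concentrations must be nonnegative")
    oa = oc * ratio
    if isinstance(oa, xr.DataArray):
        oa.name = "OA"
    return oa
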