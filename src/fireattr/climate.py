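"""Forced-signal extraction and counterfactual ("natural") climate construction.

The anthropogenic climate change (ACC) signal of a variable is estimated from
a multi-model ensemble as the ensemble mean of signed departures of each
member's 20-year moving average from that member's own 1921–1940 reference
mean. Subtracting the signal from the observed record yields the natural
counterfactual — the climate trajectory with the forced component removed but
natural variability retained.

Working from reference-relative departures (rather than absolute model
values) removes constant model biases; the 20-year low-pass suppresses
internal variability so the residual departure approximates the forced
response.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .trends import TrendResult, theil_sen_trend

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleMemberSeries",
    "ACCSignal",
    "ScenarioClimate",
    "compute_vpd",
    "saturation_vapor_pressure",
    "splice_and_annualize",
    "acc_signal_from_ensemble",
    "build_natural_scenario",
    "regrid_and_aggregate",
]

#: physical bounds re-imposed after subtracting a signal from observations
VARIABLE_BOUNDS = {
    "RH": (0.0, 100.0),
    "RHmin": (0.0, 100.0),
    "RHmax": (0.0, 100.0),
    "PRECIP": (0.0, None),
    "VPD": (0.0, None),
    "SPH": (0.0, None),
    "NDVI": (0.0, 1.0),
}


@dataclass(frozen=True)
class EnsembleMemberSeries:
    """Annual series of one variable from one climate model realization."""

    model_id: str
    variable: str
    values: pd.Series  # indexed by year, no gaps
    units: str = ""
    provenance: pd.Series | None = None  # per-year "historical" / "scenario"

    def __post_init__(self):
        years = np.asarray(self.values.index, dtype=int)
        if len(years) and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError(f"member {self.model_id}/{self.variable} has year gaps")


@dataclass(frozen=True)
class ACCSignal:
    """Per-year forced departure of one variable (ensemble mean of members)."""

    variable: str
    signal: pd.Series  # year -> departure, native units
    per_model: pd.DataFrame  # year x model_id, for spread diagnostics
    window: int = 20
    reference: tuple = (1921, 1940)
    trend: TrendResult | None = None

    @property
    def n_models(self) -> int:
        return self.per_model.shape[1]

    def ensemble_se(self) -> pd.Series:
        """Standard error of the ensemble-mean signal across members."""
        return self.per_model.std(axis=1, ddof=1) / np.sqrt(self.n_models)


@dataclass(frozen=True)
class ScenarioClimate:
    """Per-(ecoregion, year) predictor table for one climate scenario."""

    scenario: str  # "observed" | "natural"
    data: pd.DataFrame  # MultiIndex (ecoregion, year), columns = variables
    clip_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# VPD
# ---------------------------------------------------------------------------


def saturation_vapor_pressure(t_c, formula: str = "tetens"):
    """Saturation vapor pressure e_s in kPa at air temperature ``t_c`` (degC).

    "tetens": e_s = 0.6108 exp(17.27 T / (T + 237.3));
    "magnus": e_s = 0.61094 exp(17.625 T / (T + 243.04)).
    """
    t = np.asarray(t_c, dtype=float)
    if formula == "tetens":
        return 0.6108 * np.exp(17.27 * t / (t + 237.3))
    if formula == "magnus":
        return 0.61094 * np.exp(17.625 * t / (t + 243.04))
    raise ValueError(f"unknown saturation formula {formula!r}")


def compute_vpd(t_c, rh_pct, formula: str = "tetens"):
    """Vapor pressure deficit (kPa) from temperature (degC) and RH (%).

    VPD = e_s(T) * (1 - RH/100). RH outside [0, 100] — occasionally produced
    by model output — is clipped with a warning.
    """
    rh = np.asarray(rh_pct, dtype=float)
    if (rh < 0).any() or (rh > 100).any():
        n = int(((rh < 0) | (rh > 100)).sum())
        logger.warning("clipping %d RH values outside [0, 100]%%", n)
        rh = np.clip(rh, 0.0, 100.0)
    return saturation_vapor_pressure(t_c, formula) * (1.0 - rh / 100.0)


# ---------------------------------------------------------------------------
# splicing and annualization
# ---------------------------------------------------------------------------


def _annualize(series: pd.Series) -> pd.Series:
    """Monthly (DatetimeIndex/PeriodIndex) to annual means; annual passthrough."""
    if isinstance(series.index, (pd.DatetimeIndex, pd.PeriodIndex)):
        idx = series.index
        years = idx.year
        out = series.groupby(years).mean()
        out.index.name = "year"
        return out
    out = series.copy()
    out.index = pd.Index(np.asarray(series.index, dtype=int), name="year")
    return out


def splice_and_annualize(historical: pd.Series, scenario: pd.Series,
                         split_year: int = 2015, model_id: str = "",
                         variable: str = "", units: str = "") -> EnsembleMemberSeries:
    """Join a historical and a scenario segment into one continuous annual series.

    Monthly input is averaged to annual means first. The historical segment
    must end in ``split_year - 1`` and the scenario segment start in
    ``split_year``; any gap or overlap is a hard error. Per-year provenance is
    recorded.
    """
    hist = _annualize(historical)
    scen = _annualize(scenario)
    if hist.index.max() != split_year - 1 or scen.index.min() != split_year:
        raise ValueError(
            f"segments must abut at {split_year}: historical ends "
            f"{hist.index.max()}, scenario starts {scen.index.min()}"
        )
    values = pd.concat([hist, scen])
    provenance = pd.Series(
        ["historical"] * len(hist) + ["scenario"] * len(scen), index=values.index
    )
    return EnsembleMemberSeries(model_id=model_id, variable=variable, values=values,
                                units=units, provenance=provenance)


# ---------------------------------------------------------------------------
# forced signal
# ---------------------------------------------------------------------------


def _member_departure(values: pd.Series, window: int, reference: tuple,
                      labeling: str) -> pd.Series:
    ref_mean = values.loc[reference[0]: reference[1]].mean()
    rolled = values.rolling(window).mean()  # trailing window labeled by final year
    if labeling == "centered":
        rolled = rolled.shift(-(window // 2))
    return rolled - ref_mean


def acc_signal_from_ensemble(members, window: int = 20, reference: tuple = (1921, 1940),
                             target_years=None, labeling: str = "trailing",
                             alpha: float = 0.05) -> ACCSignal:
    """Ensemble-mean forced departure of one variable.

    Per member, the departure for year y is the mean over the ``window`` years
    assigned to y (trailing by default: y-window+1 .. y) minus that member's
    mean over the reference period. The ensemble signal is the arithmetic mean
    of the signed per-member departures; a Mann–Kendall test on the
    ensemble-mean signal over the target years is attached.

    Members missing the reference period are excluded with a warning; fewer
    than two usable members is an error.
    """
    members = list(members)
    if not members:
        raise ValueError("empty ensemble")
    variable = members[0].variable
    usable = []
    for m in members:
        yrs = m.values.index
        if yrs.min() > reference[0] or yrs.max() < reference[1]:
            logger.warning("excluding member %s: does not cover reference %s", m.model_id, reference)
            continue
        usable.append(m)
    if len(usable) < 2:
        raise ValueError(f"fewer than 2 usable members for {variable}")
    per_model = pd.DataFrame(
        {m.model_id: _member_departure(m.values, window, reference, labeling) for m in usable}
    )
    per_model.index.name = "year"
    if target_years is not None:
        target_years = np.asarray(list(target_years), dtype=int)
        missing = per_model.loc[target_years].isna()
        if missing.to_numpy().any():
            raise ValueError(
                f"members do not cover a full {window}-y window for all target years"
            )
        per_model = per_model.loc[target_years]
    else:
        per_model = per_model.dropna()
    signal = per_model.mean(axis=1)
    trend = theil_sen_trend(signal, alpha=alpha) if len(signal) >= 3 else None
    return ACCSignal(variable=variable, signal=signal, per_model=per_model,
                     window=window, reference=tuple(reference), trend=trend)


# ---------------------------------------------------------------------------
# natural scenario
# ---------------------------------------------------------------------------


def build_natural_scenario(observed: pd.DataFrame, signals: dict,
                           passthrough=("NDVI",)) -> ScenarioClimate:
    """Natural counterfactual: observed minus the ACC signal per variable.

    ``observed`` is indexed by (ecoregion, year) with variable columns;
    ``signals`` maps variable name to an :class:`ACCSignal` (or a plain
    year-indexed Series). Variables in ``passthrough`` (NDVI by default, whose
    variability is treated as entirely natural) and variables without a signal
    are copied unchanged. Physical bounds are re-imposed after subtraction and
    clip counts recorded.
    """
    natural = observed.copy()
    years = observed.index.get_level_values("year")
    clip_counts: dict = {}
    for var, sig in signals.items():
        if var in passthrough or var not in natural.columns:
            continue
        series = sig.signal if isinstance(sig, ACCSignal) else sig
        missing = set(years.unique()) - set(series.index)
        if missing:
            raise ValueError(f"signal for {var} missing years {sorted(missing)[:5]}")
        natural[var] = natural[var].to_numpy() - series.loc[years].to_numpy()
        bounds = VARIABLE_BOUNDS.get(var)
        if bounds is not None:
            lo, hi = bounds
            below = int((natural[var] < lo).sum()) if lo is not None else 0
            above = int((natural[var] > hi).sum()) if hi is not None else 0
            if below or above:
                clip_counts[var] = below + above
                logger.info("natural scenario: clipped %d %s values to bounds", below + above, var)
            natural[var] = natural[var].clip(lower=lo, upper=hi)
    return ScenarioClimate(scenario="natural", data=natural, clip_counts=clip_counts)


# ---------------------------------------------------------------------------
# regridding / aggregation
# ---------------------------------------------------------------------------


def regrid_and_aggregate(field: xr.DataArray, target_grid: xr.DataArray | None = None,
                         ecoregion_mask: xr.DataArray | None = None,
                         ecoregion_names=None):
    """Bilinear regrid to a target grid, or area-weighted ecoregion means.

    With ``target_grid``, returns the field bilinearly interpolated onto the
    target's lat/lon coordinates (intensive variables). With
    ``ecoregion_mask`` (integer raster, 0 = outside), returns a DataFrame of
    cos(latitude)-area-weighted means per ecoregion (rows: any leading dims
    such as year; columns: ecoregions).
    """
    if (target_grid is None) == (ecoregion_mask is None):
        raise ValueError("provide exactly one of target_grid or ecoregion_mask")
    if target_grid is not None:
        return field.interp(lat=target_grid["lat"], lon=target_grid["lon"], method="linear")
    mask = ecoregion_mask.astype(int)
    weights = np.cos(np.deg2rad(field["lat"]))
    weights = weights * xr.ones_like(field.isel({d: 0 for d in field.dims if d not in ("lat", "lon")}, drop=True))
    regions = [int(r) for r in np.unique(mask.values) if r != 0]
    cols = {}
    for r in regions:
        sel = mask == r
        if not bool(sel.any()):
            raise ValueError(f"ecoregion {r} overlaps no cells")
        w = weights.where(sel)
        num = (field.where(sel) * w).sum(("lat", "lon"))
        den = w.sum(("lat", "lon"))
        name = ecoregion_names[r - 1] if ecoregion_names else r
        cols[name] = (num / den).to_series() if num.ndim else float(num / den)
    if all(np.isscalar(v) for v in cols.values()):
        return pd.Series(cols)
    return pd.DataFrame(cols)
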