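"""Fire-occurrence records: ingestion, filtering, and stratified burned area.

Records follow the structure of point-based fire-occurrence databases: one
row per fire with a discovery date, a point location, a burned area and a
cause class. Records with a "Missing/not specified/undetermined" cause are
excluded from analysis (they are reported in the exclusion metadata); the
remaining Natural and Human records are stratified into annual burned-area
totals per (ecoregion, ignition source) and onto a regular grid.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "StratifiedBATable",
    "SkillMetrics",
    "parse_and_filter_records",
    "stratify_annual_ba",
    "skill_metrics",
    "ACRES_TO_KM2",
]

ACRES_TO_KM2 = 0.00404686

CAUSE_TO_SOURCE = {"Natural": "lightning", "Human": "human"}

REQUIRED_COLUMNS = ("record_id", "discovery_date", "lat", "lon", "cause")


@dataclass(frozen=True)
class ExclusionReport:
    """Counts and percentages of records by disposition."""

    n_total: int
    n_kept: int
    by_cause: dict
    pct_by_cause: dict
    n_missing_cause: int
    n_outside_years: int
    n_malformed: int
    conversion: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "by_cause": dict(self.by_cause),
            "pct_by_cause": dict(self.pct_by_cause),
            "n_missing_cause": self.n_missing_cause,
            "n_outside_years": self.n_outside_years,
            "n_malformed": self.n_malformed,
        }


@dataclass(frozen=True)
class StratifiedBATable:
    """Annual burned area per (ecoregion, ignition source) plus gridded totals."""

    table: pd.DataFrame  # tidy: ecoregion, source, year, ba_km2
    gridded: xr.DataArray  # (year, lat, lon) annual BA km2
    n_dropped_outside: int
    metadata: dict = field(default_factory=dict)

    def series(self, ecoregion: str, source: str) -> pd.Series:
        sub = self.table[(self.table.ecoregion == ecoregion) & (self.table.source == source)]
        return sub.set_index("year")["ba_km2"].sort_index()

    def total_km2(self) -> float:
        return float(self.table["ba_km2"].sum())


@dataclass(frozen=True)
class SkillMetrics:
    """Prediction skill of an annual burned-area series."""

    r2: float
    rmse: float
    nmb_pct: float
    extreme_year_nmb_pct: float
    n_extreme_years: int
    flags: tuple = ()


def parse_and_filter_records(path_or_df, study_years: tuple,
                             area_unit: str = "km2") -> tuple[pd.DataFrame, ExclusionReport]:
    """Read fire records; keep Natural/Human causes within the study years.

    Parameters
    ----------
    path_or_df : str, Path or DataFrame
        CSV with columns record_id, discovery_date (ISO-8601), lat, lon,
        area_km2 (or area_acres with ``area_unit="acres"``), cause.
    study_years : (first, last)
        Inclusive analysis years; records outside are excluded and counted
        separately from cause-based exclusion.
    area_unit : {"km2", "acres"}
        Input area unit; acres are converted (1 acre = 0.00404686 km^2).

    Malformed rows (unparseable date or nonpositive/missing area) are logged
    and skipped; if every row is malformed a ValueError is raised.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    area_col = "area_km2" if area_unit == "km2" else "area_acres"
    missing_cols = [c for c in REQUIRED_COLUMNS + (area_col,) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    n_total = len(df)
    if n_total == 0:
        report = ExclusionReport(0, 0, {}, {}, 0, 0, 0)
        return df.assign(year=pd.Series(dtype=int), source=pd.Series(dtype=str)), report

    dates = pd.to_datetime(df["discovery_date"], errors="coerce", format="mixed")
    area = pd.to_numeric(df[area_col], errors="coerce")
    if area_unit == "acres":
        area = area * ACRES_TO_KM2
    malformed = dates.isna() | area.isna() | (area <= 0)
    n_malformed = int(malformed.sum())
    if n_malformed:
        logger.warning("skipping %d malformed fire records", n_malformed)
    if n_malformed == n_total:
        raise ValueError("all fire records are malformed")
    df = df.loc[~malformed].copy()
    df["area_km2"] = area[~malformed]
    df["year"] = dates[~malformed].dt.year

    by_cause = df["cause"].value_counts().to_dict()
    pct_by_cause = {k: 100.0 * v / len(df) for k, v in by_cause.items()}
    cause_ok = df["cause"].isin(CAUSE_TO_SOURCE)
    n_missing_cause = int((~cause_ok).sum())
    df = df.loc[cause_ok]
    in_years = df["year"].between(study_years[0], study_years[1])
    n_outside = int((~in_years).sum())
    df = df.loc[in_years].copy()
    df["source"] = df["cause"].map(CAUSE_TO_SOURCE)
    report = ExclusionReport(
        n_total=n_total,
        n_kept=len(df),
        by_cause=by_cause,
        pct_by_cause=pct_by_cause,
        n_missing_cause=n_missing_cause,
        n_outside_years=n_outside,
        n_malformed=n_malformed,
        conversion={"acres_to_km2": ACRES_TO_KM2} if area_unit == "acres" else {},
    )
    return df.reset_index(drop=True), report


def _cell_edges(centers: np.ndarray) -> np.ndarray:
    step = centers[1] - centers[0]
    return np.concatenate([centers - step / 2, [centers[-1] + step / 2]])


def stratify_annual_ba(records: pd.DataFrame, ecoregion_mask: xr.DataArray,
                       years: tuple, ecoregion_names=None) -> StratifiedBATable:
    """Stratify record areas into (ecoregion, source, year) totals and a grid.

    Points are assigned to cells by half-open intervals [west, east) x
    [south, north); records outside the grid or in cells with mask value 0
    are dropped with a warning count. The stratification is a partition:
    kept + dropped area equals the input total exactly.
    """
    lat = ecoregion_mask["lat"].values
    lon = ecoregion_mask["lon"].values
    year_range = np.arange(years[0], years[1] + 1)
    grid = np.zeros((len(year_range), len(lat), len(lon)))

    if len(records) == 0:
        table = pd.DataFrame(columns=["ecoregion", "source", "year", "ba_km2"])
        gridded = _grid_da(grid, year_range, lat, lon)
        return StratifiedBATable(table=table, gridded=gridded, n_dropped_outside=0)

    lat_edges = _cell_edges(lat)
    lon_edges = _cell_edges(lon)
    # np.digitize with right=False gives half-open [edge_i, edge_{i+1})
    iy = np.digitize(records["lat"].to_numpy(), lat_edges) - 1
    ix = np.digitize(records["lon"].to_numpy(), lon_edges) - 1
    inside = (iy >= 0) & (iy < len(lat)) & (ix >= 0) & (ix < len(lon))
    eco_idx = np.full(len(records), 0, dtype=int)
    eco_idx[inside] = ecoregion_mask.values[iy[inside], ix[inside]]
    keep = inside & (eco_idx > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d records outside the grid/ecoregions", n_dropped)

    kept = records.loc[keep].copy()
    kept["eco_idx"] = eco_idx[keep]
    if ecoregion_names is not None:
        kept["ecoregion"] = [ecoregion_names[i - 1] for i in kept["eco_idx"]]
    else:
        kept["ecoregion"] = kept["eco_idx"].astype(str)
    table = (
        kept.groupby(["ecoregion", "source", "year"], as_index=False)["area_km2"]
        .sum()
        .rename(columns={"area_km2": "ba_km2"})
    )
    yi = kept["year"].to_numpy() - years[0]
    np.add.at(grid, (yi, iy[keep], ix[keep]), kept["area_km2"].to_numpy())
    gridded = _grid_da(grid, year_range, lat, lon)
    meta = {
        "kept_area_km2": float(kept["area_km2"].sum()),
        "dropped_area_km2": float(records.loc[~keep, "area_km2"].sum()),
    }
    return StratifiedBATable(table=table, gridded=gridded,
                             n_dropped_outside=n_dropped, metadata=meta)


def _grid_da(grid, years, lat, lon) -> xr.DataArray:
    return xr.DataArray(
        grid, coords={"year": years, "lat": lat, "lon": lon},
        dims=("year", "lat", "lon"), name="burned_area", attrs={"units": "km2"},
    )


def r_squared(pred, obs, method: str = "pearson") -> float:
    """R^2 between predicted and observed series.

    "pearson" (default): squared Pearson correlation — symmetric, matches the
    common usage for reporting interannual-variability skill. "ss":
    1 - SSE/SST, which penalizes bias as well as decorrelation.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if method == "pearson":
        # an (almost) constant series has no meaningful correlation; the
        # relative guard also catches numerically-degenerate predictions
        if np.std(pred) <= 1e-8 * (1 + abs(np.mean(pred))) or np.std(obs) == 0:
            return float("nan")
        return float(np.corrcoef(pred, obs)[0, 1] ** 2)
    if method == "ss":
        sst = float(((obs - obs.mean()) ** 2).sum())
        if sst == 0:
            return float("nan")
        return 1.0 - float(((obs - pred) ** 2).sum()) / sst
    raise ValueError(f"unknown R^2 method {method!r}")


def skill_metrics(pred, obs, extreme_pct: float = 80.0,
                  r2_method: str = "pearson") -> SkillMetrics:
    """Skill of a predicted annual series against observations.

    NMB = 100 (sum pred - sum obs) / sum obs over all years; the extreme-year
    NMB restricts both series to years where the observation exceeds its own
    ``extreme_pct`` percentile.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(obs) < 2:
        raise ValueError("series must have equal length >= 2")
    flags = []
    r2 = r_squared(pred, obs, r2_method)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    nmb = 100.0 * (pred.sum() - obs.sum()) / obs.sum()
    thresh = np.percentile(obs, extreme_pct)
    ext = obs > thresh
    if ext.sum() < 1:
        extreme_nmb = float("nan")
        flags.append("no_extreme_years")
    else:
        extreme_nmb = 100.0 * (pred[ext].sum() - obs[ext].sum()) / obs[ext].sum()
    return SkillMetrics(r2=r2, rmse=rmse, nmb_pct=float(nmb),
                        extreme_year_nmb_pct=float(extreme_nmb),
                        n_extreme_years=int(ext.sum()), flags=tuple(flags))
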