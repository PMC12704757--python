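"""Synthetic inputs with known latent truth for the attribution chain.

This module emulates the statistical structure of the real data sources the
attribution method was designed for — a fire-occurrence database, an observed
gridded climate record, a multi-model climate ensemble, a gridded
dry-matter/emissions inventory, and chemical-transport-model concentration
fields — while keeping the generating process fully known:

* every climate variable is a shared forced trend + per-model bias +
  internal variability (ensemble members), or forced trend + one natural
  realization (the "observed" record);
* annual burned area per (ecoregion, ignition source) is a known response to
  ecoregion-mean climate and NDVI with multiplicative lognormal noise;
* dry matter burned is linear in burned area; concentrations are linear in
  emissions through an explicit mass-conserving smoothing kernel.

Because the forced component and the noise-free response are retained, the
ground-truth anthropogenic (ACC) fraction of burned area is computable
exactly (:func:`true_acc_fraction`), enabling end-to-end recovery tests.

All randomness flows from one master seed through named substreams
(:mod:`fireattr.streams`), so regenerating one dataset never perturbs another.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .streams import substream

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "ResponseSpec",
    "SyntheticTruth",
    "gen_climate_ensemble",
    "gen_observed_series",
    "gen_burned_area_records",
    "gen_emissions_inputs",
    "gen_concentration_fields",
    "true_acc_fraction",
    "build_transport_matrix",
]

#: default ecoregion labels (five aggregated western-US regions)
ECOREGIONS = (
    "NW_Forested_Mts",
    "Mediterranean_CA",
    "Cold_Deserts",
    "SW_Forested_Mts",
    "Central_Prairies",
)

SOURCES = ("lightning", "human")

CAUSE_BY_SOURCE = {"lightning": "Natural", "human": "Human"}


@dataclass(frozen=True)
class VariableSpec:
    """Generating parameters of one climate variable.

    ``forced_slope`` is the rate of the forced (ACC) component in native
    units per year after ``SyntheticTruth.breakpoint_year``; the component is
    flat before the breakpoint (or linear over the whole record when the
    truth's ``trend_shape`` is "linear").
    """

    baseline: float
    forced_slope: float
    nv_sd: float
    units: str
    ar1: float = 0.0
    bounds: tuple | None = None
    ecoregion_sd: float = 0.0  # spread of per-ecoregion baseline offsets

    def __post_init__(self):
        if self.nv_sd < 0:
            raise ValueError("natural-variability SD must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


@dataclass(frozen=True)
class ResponseSpec:
    """Burned-area response of one (ecoregion, ignition source) stratum.

    The linear predictor is ``eta = intercept + sum_i beta_i * (X_i - center_i)``
    so the intercept is the response at climatological-normal conditions.
    ``kind`` is "linear" (BA = eta clipped at 0, km^2) or "loglinear"
    (BA = exp(eta)); observed annual burned area multiplies the deterministic
    response by mean-one lognormal noise with log-SD ``noise_sd``.
    """

    predictors: tuple
    beta: tuple
    intercept: float
    centers: tuple = ()
    kind: str = "linear"
    noise_sd: float = 0.2

    def __post_init__(self):
        if len(self.predictors) != len(self.beta):
            raise ValueError("beta must match predictors")
        if self.centers and len(self.centers) != len(self.predictors):
            raise ValueError("centers must match predictors")
        if not self.centers:
            object.__setattr__(self, "centers", tuple(0.0 for _ in self.predictors))
        if self.kind not in ("linear", "loglinear"):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    def deterministic(self, X: pd.DataFrame) -> np.ndarray:
        """Noise-free response evaluated on predictor columns of ``X``."""
        eta = self.intercept + sum(
            b * (X[p].to_numpy(dtype=float) - c)
            for p, b, c in zip(self.predictors, self.beta, self.centers)
        )
        if self.kind == "loglinear":
            return np.exp(eta)
        neg = eta < 0
        if neg.any():
            logger.debug("clipping %d negative response values at 0", int(neg.sum()))
        return np.clip(eta, 0.0, None)


def _default_variables() -> dict:
    # Magnitudes chosen to resemble ecoregion-mean annual statistics of the
    # western US: forced warming emerging mid-century (consistent with a
    # 1921-1940 "preindustrial-adjacent" reference), end-of-record departures
    # of ~1.5 K in Tmax and ~0.15 kPa in VPD, interannual SDs of similar order.
    return {
        "Tmax": VariableSpec(25.0, 0.020, 0.6, "degC", ecoregion_sd=0.8),
        "VPD": VariableSpec(1.2, 0.002, 0.08, "kPa", bounds=(0.0, None), ecoregion_sd=0.05),
        "PRECIP": VariableSpec(2.0, 0.0, 0.35, "mm", bounds=(0.0, None), ecoregion_sd=0.3),
        "RHmin": VariableSpec(30.0, -0.015, 2.5, "%", bounds=(0.0, 100.0), ecoregion_sd=3.0),
        "NDVI": VariableSpec(0.45, 0.0, 0.03, "1", bounds=(0.0, 1.0), ecoregion_sd=0.05),
    }


def _default_responses() -> dict:
    # Linear responses to Tmax and VPD (lightning more climate-sensitive than
    # human-ignited fire, as in the real record); NDVI enters the human
    # response as a fuel-load proxy. Intercepts (the response under
    # climatological-normal conditions) vary by ecoregion so the true ACC
    # fractions span a wide known range.
    base_lightning = {"NW_Forested_Mts": 260.0, "Mediterranean_CA": 420.0,
                      "Cold_Deserts": 300.0, "SW_Forested_Mts": 200.0,
                      "Central_Prairies": 360.0}
    spec = {}
    strength = {"lightning": 1.0, "human": 0.7}
    for eco in ECOREGIONS:
        b0 = base_lightning.get(eco, 300.0)
        for src in SOURCES:
            k = strength[src]
            if src == "lightning":
                spec[(eco, src)] = ResponseSpec(
                    predictors=("Tmax", "VPD"),
                    beta=(k * 60.0, k * 1100.0),
                    centers=(25.0, 1.2),
                    intercept=b0,
                    noise_sd=0.10,
                )
            else:
                spec[(eco, src)] = ResponseSpec(
                    predictors=("Tmax", "VPD", "NDVI"),
                    beta=(k * 60.0, k * 900.0, k * 2500.0),
                    centers=(25.0, 1.2, 0.45),
                    intercept=0.9 * b0,
                    noise_sd=0.10,
                )
    return spec


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent parameters of the synthetic study region.

    Identical truth + master seed reproduce every generated dataset
    bit-for-bit.
    """

    master_seed: int = 0
    grid_shape: tuple = (20, 20)
    n_ecoregions: int = 5
    ecoregions: tuple = ECOREGIONS
    lat_range: tuple = (31.0, 49.0)
    lon_range: tuple = (-125.0, -102.0)
    ensemble_years: tuple = (1920, 2020)
    analysis_years: tuple = (1992, 2020)
    breakpoint_year: int = 1945
    trend_shape: str = "piecewise"  # or "linear"
    variables: dict = field(default_factory=_default_variables)
    model_bias_sd: float = 0.8
    model_internal_sd_factor: float = 1.0  # ensemble internal variability / observed nv_sd
    response_spec: dict = field(default_factory=_default_responses)
    dm_ba_slope: float = 2.0e6  # kg dry matter per km2 burned
    dm_ba_intercept: float = 0.0
    dm_noise_frac: float = 0.1
    emission_factors: dict = field(
        default_factory=lambda: {
            # g species per kg dry matter, illustrative literature-scale values
            "forest": {"OC": 9.6, "BC": 0.52},
            "savanna": {"OC": 2.6, "BC": 0.37},
        }
    )
    forest_fraction_by_ecoregion: dict = field(
        default_factory=lambda: {
            "NW_Forested_Mts": 0.85,
            "Mediterranean_CA": 0.45,
            "Cold_Deserts": 0.25,
            "SW_Forested_Mts": 0.8,
            "Central_Prairies": 0.15,
        }
    )
    transport_length: float = 2.0  # kernel e-folding length, grid cells
    # calibrated so domain-mean smoke is a sizable fraction of the ~2 ug m-3
    # background, as observed for fire-season PM2.5 in the western US
    transport_gain: float = 2.0e-6  # ug m-3 per kg emitted
    background_level: float = 2.0  # ug m-3 nonfire PM2.5
    missing_cause_fraction: float = 0.08
    records_per_stratum_year: int = 12

    def __post_init__(self):
        if self.model_bias_sd < 0 or self.dm_noise_frac < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.missing_cause_fraction < 0 or self.missing_cause_fraction >= 1:
            raise ValueError("missing-cause fraction must be in [0, 1)")
        for table in self.emission_factors.values():
            if any(v < 0 for v in table.values()):
                raise ValueError("emission factors must be >= 0")
        if self.trend_shape not in ("piecewise", "linear"):
            raise ValueError(f"unknown trend shape {self.trend_shape!r}")
        if len(self.ecoregions) != self.n_ecoregions:
            object.__setattr__(self, "ecoregions", tuple(self.ecoregions)[: self.n_ecoregions])

    # -- geography -----------------------------------------------------------

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid_shape
        lat = np.linspace(*self.lat_range, ny)
        lon = np.linspace(*self.lon_range, nx)
        return lat, lon

    def ecoregion_mask(self) -> xr.DataArray:
        """Integer raster of contiguous ecoregions (1..n; 0 would be outside).

        Ecoregions are vertical longitude bands, so every region is contiguous
        and every cell belongs to exactly one region.
        """
        lat, lon = self.grid_coords()
        ny, nx = self.grid_shape
        band = np.minimum((np.arange(nx) * self.n_ecoregions) // nx, self.n_ecoregions - 1)
        mask = np.tile(band + 1, (ny, 1))
        return xr.DataArray(
            mask.astype(np.int32),
            coords={"lat": lat, "lon": lon},
            dims=("lat", "lon"),
            name="ecoregion",
            attrs={"flag_values": list(range(1, self.n_ecoregions + 1)),
                   "flag_meanings": " ".join(self.ecoregions)},
        )

    def population(self) -> xr.DataArray:
        """Static population raster: lognormal field with a few dense cells."""
        rng = substream(self.master_seed, "population")
        lat, lon = self.grid_coords()
        pop = rng.lognormal(mean=8.0, sigma=1.5, size=self.grid_shape)
        # a handful of "urban" hotspots
        for _ in range(5):
            i, j = rng.integers(0, self.grid_shape[0]), rng.integers(0, self.grid_shape[1])
            pop[i, j] *= rng.uniform(30, 100)
        return xr.DataArray(pop, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"),
                            name="population", attrs={"units": "persons"})

    # -- forced component ----------------------------------------------------

    def forced_component(self, variable: str, years) -> np.ndarray:
        """Forced (ACC) departure of ``variable`` relative to the pre-breakpoint state."""
        spec = self.variables[variable]
        years = np.asarray(years, dtype=float)
        if self.trend_shape == "linear":
            return spec.forced_slope * (years - self.ensemble_years[0])
        return spec.forced_slope * np.clip(years - self.breakpoint_year, 0.0, None)

    def expected_acc_signal(self, variable: str, years, window: int = 20,
                            reference: tuple = (1921, 1940)) -> np.ndarray:
        """Estimand of the moving-average signal method for this truth.

        The noise-free forced component passed through the same trailing
        ``window``-year mean and reference differencing the estimator applies;
        the ensemble estimate converges to this as the ensemble grows. Because
        of the low-pass filter it lags the instantaneous forced component by
        roughly (window - 1) / 2 years of trend.
        """
        years = np.asarray(years, dtype=float)
        ref_years = np.arange(reference[0], reference[1] + 1)
        ref_mean = self.forced_component(variable, ref_years).mean()
        out = np.empty(len(years))
        for i, y in enumerate(years):
            win = np.arange(y - window + 1, y + 1)
            out[i] = self.forced_component(variable, win).mean() - ref_mean
        return out

    def to_dict(self) -> dict:
        """JSON-serializable dump of the latent parameters."""
        return {
            "master_seed": self.master_seed,
            "grid_shape": list(self.grid_shape),
            "ecoregions": list(self.ecoregions),
            "ensemble_years": list(self.ensemble_years),
            "analysis_years": list(self.analysis_years),
            "breakpoint_year": self.breakpoint_year,
            "trend_shape": self.trend_shape,
            "variables": {
                k: {"baseline": v.baseline, "forced_slope": v.forced_slope,
                    "nv_sd": v.nv_sd, "units": v.units, "ar1": v.ar1}
                for k, v in self.variables.items()
            },
            "model_bias_sd": self.model_bias_sd,
            "response_spec": {
                f"{e}|{s}": {"predictors": list(r.predictors), "beta": list(r.beta),
                             "intercept": r.intercept, "kind": r.kind, "noise_sd": r.noise_sd}
                for (e, s), r in self.response_spec.items()
            },
            "dm_ba_slope": self.dm_ba_slope,
            "dm_ba_intercept": self.dm_ba_intercept,
            "emission_factors": self.emission_factors,
            "transport_length": self.transport_length,
            "background_level": self.background_level,
            "missing_cause_fraction": self.missing_cause_fraction,
        }

    def with_seed(self, master_seed: int) -> "SyntheticTruth":
        return replace(self, master_seed=master_seed)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------


def _ar1_noise(rng, n: int, sd: float, phi: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, n)
    if phi == 0.0 or sd == 0.0:
        return eps
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(1 - phi**2) * np.sqrt(1 - phi**2)  # stationary start
    out[0] = rng.normal(0.0, sd / np.sqrt(1 - phi**2))
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def gen_climate_ensemble(truth: SyntheticTruth, n_models: int = 12, years=None,
                         variables=None) -> dict:
    """Pseudo multi-model ensemble of annual series per variable.

    Each member is the shared forced component + a model-specific constant
    offset + independent internal variability. Returns ``{variable: [
    EnsembleMemberSeries, ...]}``; the true forced component is available from
    ``truth.forced_component`` for recovery tests.
    """
    from .climate import EnsembleMemberSeries  # local import avoids a cycle

    if n_models < 2:
        raise ValueError("an ensemble needs n_models >= 2")
    if years is None:
        years = np.arange(truth.ensemble_years[0], truth.ensemble_years[1] + 1)
    else:
        years = np.asarray(years)
    if len(years) < 22:
        raise ValueError(
            "year range shorter than the reference period plus one moving window; "
            f"got {len(years)} years, need at least 22"
        )
    variables = list(variables or truth.variables)
    out: dict = {}
    for var in variables:
        spec = truth.variables[var]
        forced = spec.baseline + truth.forced_component(var, years)
        members = []
        for m in range(n_models):
            rng = substream(truth.master_seed, f"ensemble/{var}/model{m}")
            bias = rng.normal(0.0, truth.model_bias_sd) if truth.model_bias_sd > 0 else 0.0
            noise = _ar1_noise(rng, len(years), spec.nv_sd * truth.model_internal_sd_factor,
                               spec.ar1)
            values = pd.Series(forced + bias + noise, index=pd.Index(years, name="year"))
            provenance = pd.Series(
                np.where(years <= 2014, "historical", "scenario"), index=values.index
            )
            members.append(
                EnsembleMemberSeries(model_id=f"model{m:02d}", variable=var,
                                     values=values, units=spec.units, provenance=provenance)
            )
        out[var] = members
    return out


def gen_observed_series(truth: SyntheticTruth, years=None) -> pd.DataFrame:
    """Observed ecoregion-mean climate + NDVI: forced component + one natural realization.

    Returns a DataFrame indexed by (ecoregion, year) with one column per
    variable. NDVI is stationary (no forced component) — its interannual
    variability is treated as entirely natural.
    """
    if years is None:
        years = np.arange(truth.analysis_years[0], truth.analysis_years[1] + 1)
    else:
        years = np.asarray(years)
    geo = substream(truth.master_seed, "geography")
    offsets = {
        eco: {var: geo.normal(0.0, truth.variables[var].ecoregion_sd)
              for var in truth.variables}
        for eco in truth.ecoregions
    }
    frames = []
    for eco in truth.ecoregions:
        data = {}
        for var, spec in truth.variables.items():
            rng = substream(truth.master_seed, f"observed/{var}/{eco}")
            natural = _ar1_noise(rng, len(years), spec.nv_sd, spec.ar1)
            series = spec.baseline + offsets[eco][var] + truth.forced_component(var, years) + natural
            if spec.bounds is not None:
                lo, hi = spec.bounds
                series = np.clip(series, lo if lo is not None else -np.inf,
                                 hi if hi is not None else np.inf)
            data[var] = series
        frames.append(pd.DataFrame(data, index=pd.MultiIndex.from_product(
            [[eco], years], names=["ecoregion", "year"])))
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# burned area
# ---------------------------------------------------------------------------


def gen_burned_area_records(truth: SyntheticTruth, observed: pd.DataFrame,
                            seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fire records plus the true annual burned-area table.

    Returns ``(records, truth_table)``. ``truth_table`` is tidy with columns
    (ecoregion, source, year, ba_km2): the noisy annual totals per stratum.
    Record areas within each stratum-year sum exactly to the table entry.
    A configurable fraction of *additional* records carries the "Missing"
    cause label; their areas are not part of any stratum total.
    """
    seed = truth.master_seed if seed is None else seed
    years = observed.index.get_level_values("year").unique().to_numpy()
    mask = truth.ecoregion_mask()
    lat, lon = truth.grid_coords()
    eco_cells = {
        eco: np.argwhere(mask.values == i + 1) for i, eco in enumerate(truth.ecoregions)
    }
    dlat = lat[1] - lat[0]
    dlon = lon[1] - lon[0]

    table_rows = []
    rec_rows = []
    rid = 0
    for (eco, src), resp in truth.response_spec.items():
        rng = substream(seed, f"ba/{eco}/{src}")
        X = observed.loc[eco]
        det = resp.deterministic(X.loc[years])
        if resp.noise_sd > 0:
            noise = rng.lognormal(-resp.noise_sd**2 / 2.0, resp.noise_sd, len(years))
        else:
            noise = np.ones(len(years))
        ba = det * noise
        for y, total in zip(years, ba):
            table_rows.append((eco, src, int(y), float(total)))
            if total <= 0:
                continue
            n_rec = max(1, int(rng.poisson(truth.records_per_stratum_year)))
            w = rng.dirichlet(np.ones(n_rec) * 0.8)
            areas = total * w
            areas[-1] = total - areas[:-1].sum()  # exact conservation
            cells = eco_cells[eco][rng.integers(0, len(eco_cells[eco]), n_rec)]
            day = rng.integers(0, 365, n_rec)
            for a, (ci, cj), d in zip(areas, cells, day):
                rec_rows.append(
                    dict(
                        record_id=f"F{rid:07d}",
                        discovery_date=(pd.Timestamp(int(y), 1, 1) + pd.Timedelta(days=int(d))).date().isoformat(),
                        lat=float(lat[ci] + rng.uniform(-0.49, 0.49) * dlat),
                        lon=float(lon[cj] + rng.uniform(-0.49, 0.49) * dlon),
                        area_km2=float(max(a, 1e-9)),
                        cause=CAUSE_BY_SOURCE[src],
                    )
                )
                rid += 1
    # extra missing-cause records, excluded from the truth table by design
    frac = truth.missing_cause_fraction
    if frac > 0 and rec_rows:
        rng = substream(seed, "ba/missing")
        n_missing = int(round(frac / (1.0 - frac) * len(rec_rows)))
        all_cells = np.argwhere(mask.values > 0)
        for _ in range(n_missing):
            ci, cj = all_cells[rng.integers(0, len(all_cells))]
            y = int(rng.choice(years))
            rec_rows.append(
                dict(
                    record_id=f"F{rid:07d}",
                    discovery_date=(pd.Timestamp(y, 1, 1) + pd.Timedelta(days=int(rng.integers(0, 365)))).date().isoformat(),
                    lat=float(lat[ci]),
                    lon=float(lon[cj]),
                    area_km2=float(rng.lognormal(-2.0, 1.0)),
                    cause="Missing",
                )
            )
            rid += 1
    records = pd.DataFrame(rec_rows)
    if not records.empty:
        records = records.sample(frac=1.0, random_state=substream(seed, "ba/shuffle").integers(2**31)).reset_index(drop=True)
    truth_table = pd.DataFrame(table_rows, columns=["ecoregion", "source", "year", "ba_km2"])
    return records, truth_table


# ---------------------------------------------------------------------------
# emissions and concentrations
# ---------------------------------------------------------------------------


def gen_emissions_inputs(truth: SyntheticTruth, ba_table: pd.DataFrame):
    """Gridded annual dry matter burned + fire-type fractions + EF table.

    Annual ecoregion DM = slope * BA + intercept + noise, disaggregated onto
    the grid with a spatial pattern that is fixed across scenarios (drawn once
    from the master seed). Returns ``(dm, type_fractions, ef_table)`` where
    ``dm`` is an (year, lat, lon) DataArray in kg and ``type_fractions`` maps
    land types to static (lat, lon) fraction fields summing to 1.
    """
    mask = truth.ecoregion_mask()
    lat, lon = truth.grid_coords()
    years = np.sort(ba_table["year"].unique())
    ba_total = ba_table.groupby(["ecoregion", "year"])["ba_km2"].sum()

    rng = substream(truth.master_seed, "emissions/space")
    pattern = np.zeros(truth.grid_shape)
    for i, eco in enumerate(truth.ecoregions):
        cells = mask.values == i + 1
        w = rng.dirichlet(np.ones(int(cells.sum())))
        pattern[cells] = w

    rng_t = substream(truth.master_seed, "emissions/noise")
    dm = np.zeros((len(years),) + truth.grid_shape)
    for i, eco in enumerate(truth.ecoregions):
        cells = mask.values == i + 1
        w = pattern[cells]
        for t, y in enumerate(years):
            ba = float(ba_total.get((eco, int(y)), 0.0))
            total = truth.dm_ba_slope * ba + truth.dm_ba_intercept
            if truth.dm_noise_frac > 0:
                total += rng_t.normal(0.0, truth.dm_noise_frac * max(total, 0.0))
            if total < 0:
                logger.debug("clipping negative DM total for %s year %d", eco, y)
                total = 0.0
            dm[t][cells] = total * w
    dm_da = xr.DataArray(
        dm, coords={"year": years, "lat": lat, "lon": lon},
        dims=("year", "lat", "lon"), name="dry_matter", attrs={"units": "kg"},
    )
    forest = xr.zeros_like(mask, dtype=float)
    for i, eco in enumerate(truth.ecoregions):
        forest = forest.where(mask != i + 1, truth.forest_fraction_by_ecoregion.get(eco, 0.5))
    type_fractions = {"forest": forest, "savanna": 1.0 - forest}
    return dm_da, type_fractions, dict(truth.emission_factors)


def build_transport_matrix(truth: SyntheticTruth) -> np.ndarray:
    """Mass-conserving Gaussian smoothing kernel over grid cells.

    Returns W of shape (ncell, ncell): column j holds the distribution of
    mass emitted in cell j over all cells; each column sums to 1 so domain
    totals are conserved exactly and downstream share identities are exact.
    """
    ny, nx = truth.grid_shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    W = np.exp(-d2 / (2.0 * truth.transport_length**2))
    W /= W.sum(axis=0, keepdims=True)
    return W


def gen_concentration_fields(emissions_obs: xr.DataArray, emissions_nat: xr.DataArray,
                             truth: SyntheticTruth) -> dict:
    """CTL/NAT/BKG annual-mean PM2.5 fields from the toy linear transport surrogate.

    conc = background + gain * W @ emissions; BKG has zero fire emissions.
    Linearity and kernel mass conservation make the downstream smoke
    decomposition and share identities exact.
    """
    if emissions_obs.shape != emissions_nat.shape or not np.array_equal(
        emissions_obs["lat"], emissions_nat["lat"]
    ):
        raise ValueError("observed and natural emissions must share a grid")
    W = build_transport_matrix(truth)
    rng = substream(truth.master_seed, "background")
    bkg_pattern = truth.background_level * (1.0 + 0.3 * rng.standard_normal(truth.grid_shape))
    bkg_pattern = np.clip(bkg_pattern, 0.1, None)

    def smoke(em: xr.DataArray) -> np.ndarray:
        flat = em.values.reshape(em.sizes["year"], -1)
        return (truth.transport_gain * flat @ W.T).reshape(em.shape)

    years = emissions_obs["year"].values
    coords = {"year": years, "lat": emissions_obs["lat"].values, "lon": emissions_obs["lon"].values}
    bkg = xr.DataArray(np.broadcast_to(bkg_pattern, emissions_obs.shape).copy(),
                       coords=coords, dims=("year", "lat", "lon"), name="pm25",
                       attrs={"units": "ug m-3", "experiment": "BKG"})
    ctl = bkg + smoke(emissions_obs)
    nat = bkg + smoke(emissions_nat)
    ctl.attrs.update(units="ug m-3", experiment="CTL")
    nat.attrs.update(units="ug m-3", experiment="NAT")
    return {"CTL": ctl, "NAT": nat, "BKG": bkg}


# ---------------------------------------------------------------------------
# truth oracle
# ---------------------------------------------------------------------------


def true_acc_fraction(truth: SyntheticTruth, observed: pd.DataFrame,
                      years=None) -> pd.DataFrame:
    """Ground-truth ACC fraction of burned area per (ecoregion, source), percent.

    Evaluates the noise-free response once with the full observed climate and
    once with the forced component subtracted (NDVI untouched); the fraction
    is 100 * sum(full - counterfactual) / sum(full). Independent of any noise
    seed by construction.
    """
    if years is None:
        years = np.arange(truth.analysis_years[0], truth.analysis_years[1] + 1)
    years = np.asarray(years)
    rows = []
    for (eco, src), resp in truth.response_spec.items():
        X = observed.loc[eco].loc[years]
        Xcf = X.copy()
        for var in truth.variables:
            if var == "NDVI" or var not in Xcf.columns:
                continue
            Xcf[var] = Xcf[var] - truth.forced_component(var, years)
            spec = truth.variables[var]
            if spec.bounds is not None:
                lo, hi = spec.bounds
                Xcf[var] = Xcf[var].clip(lower=lo, upper=hi)
        full = resp.deterministic(X)
        cf = resp.deterministic(Xcf)
        tot = full.sum()
        if tot <= 0:
            rows.append((eco, src, np.nan, True))
        else:
            rows.append((eco, src, 100.0 * (tot - cf.sum()) / tot, False))
    return pd.DataFrame(rows, columns=["ecoregion", "source", "acc_fraction_pct", "undefined"]) \
        .set_index(["ecoregion", "source"])
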