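"""Gaussian-process models of annual burned area and the ACC attribution step.

One model is fitted per (ecoregion, ignition source) stratum: annual total
burned area regressed on ecoregion-mean climate predictors and NDVI. The
interface follows the model/results convention of statistical packages:
:class:`BurnedAreaGP` holds data and configuration, ``fit()`` returns a
:class:`BurnedAreaGPResults` carrying the fitted process, cross-validated
skill, and methods for scenario prediction, Shapley importances, partial
dependence and summary tables.

Attribution compares predictions under the observed climate with predictions
under the natural counterfactual; the ACC fraction is the difference of the
scenario totals relative to the observed-scenario total.

The default kernel adds a linear (dot-product) term to an anisotropic
squared-exponential plus white noise. The linear term controls behavior under
the counterfactual shift, which moves predictors beyond the training
envelope where a pure squared-exponential process reverts to its prior mean
and systematically understates the forced response.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    Matern,
    WhiteKernel,
)

from .fire_records import r_squared
from .shapley import mean_abs_importance_pct, shapley_values

logger = logging.getLogger(__name__)

__all__ = [
    "BurnedAreaGP",
    "BurnedAreaGPResults",
    "SelectionResult",
    "AccContribution",
    "select_predictors",
    "acc_contribution",
    "driver_exclusion_experiment",
    "detrend_experiment",
]

MAX_CANDIDATES = 20


def make_kernel(name: str, n_features: int):
    """Kernel factory: "rbf+linear" (default), "rbf", "matern52", or "linear".

    The pure "linear" kernel yields a posterior mean linear in the inputs
    (Bayesian linear regression), useful as an exact-additivity oracle.
    """
    rbf_part = ConstantKernel(1.0, (1e-5, 1e5)) * RBF(
        np.ones(n_features), (1e-2, 1e5)
    )
    if name == "matern52":
        rbf_part = ConstantKernel(1.0, (1e-5, 1e5)) * Matern(
            np.ones(n_features), (1e-2, 1e5), nu=2.5
        )
    white = WhiteKernel(0.1, (1e-8, 1e1))
    linear = ConstantKernel(0.1, (1e-5, 1e5)) * DotProduct(1e-3, (1e-5, 1e3))
    if name in ("rbf", "matern52"):
        return rbf_part + white
    if name == "rbf+linear":
        return rbf_part + linear + white
    if name == "linear":
        return linear + ConstantKernel(0.1, (1e-5, 1e5)) + white
    raise ValueError(f"unknown kernel {name!r}")


def _folds(n: int, k: int, scheme: str, seed: int):
    idx = np.arange(n)
    if scheme == "random":
        idx = np.random.default_rng(seed).permutation(n)
    elif scheme != "blocked":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    return np.array_split(idx, k)


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.constant = self.std == 0
        self.std = np.where(self.constant, 1.0, self.std)

    def transform(self, X):
        return (X - self.mean) / self.std


class BurnedAreaGP:
    """Gaussian-process regression of annual burned area on climate predictors.

    Parameters
    ----------
    endog : array-like or Series
        Annual burned area (km^2), one value per training year.
    exog : DataFrame
        Predictors; the column order defines the feature order.
    name : str, optional
        Label (e.g. "NW_Forested_Mts/lightning") used in summaries.
    kernel : str
        "rbf+linear" (default), "rbf" or "matern52".
    log_target : bool
        Model log1p(burned area) instead of raw area; useful for
        heavy-tailed series where extreme years dominate the variance.
    """

    def __init__(self, endog, exog: pd.DataFrame, name: str | None = None,
                 kernel: str = "rbf+linear", log_target: bool = False):
        self.exog = pd.DataFrame(exog).astype(float)
        self.endog = pd.Series(np.asarray(endog, dtype=float), index=self.exog.index)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        self.name = name or "burned_area"
        self.kernel_name = kernel
        self.log_target = log_target
        self.predictor_names = list(self.exog.columns)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, target: str, predictors, **kwargs):
        return cls(data[target], data[list(predictors)], **kwargs)

    # -- fitting -------------------------------------------------------------

    def _target(self) -> np.ndarray:
        y = self.endog.to_numpy()
        return np.log1p(y) if self.log_target else y

    def _fit_gp(self, X: np.ndarray, y: np.ndarray, seed: int, n_restarts: int):
        sx = _Standardizer(X)
        sy = _Standardizer(y.reshape(-1, 1))
        gp = GaussianProcessRegressor(
            kernel=make_kernel(self.kernel_name, X.shape[1]),
            n_restarts_optimizer=n_restarts,
            normalize_y=False,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(sx.transform(X), sy.transform(y.reshape(-1, 1)).ravel())
        return gp, sx, sy

    def fit(self, seed: int = 0, n_restarts: int = 5, cv: int = 5,
            cv_scheme: str = "blocked") -> "BurnedAreaGPResults":
        """Fit with k-fold cross-validated skill, then refit on all years.

        Standardization constants are computed on the training folds only;
        out-of-fold predictions are pooled before computing CV R^2 and RMSE.
        """
        X = self.exog.to_numpy()
        y = self._target()
        n = len(y)
        if n < cv:
            raise ValueError(f"need at least {cv} training years for {cv}-fold CV")
        pooled = np.empty(n)
        for fold in _folds(n, cv, cv_scheme, seed):
            train = np.setdiff1d(np.arange(n), fold)
            gp, sx, sy = self._fit_gp(X[train], y[train], seed, max(1, n_restarts // 2))
            pred_s = gp.predict(sx.transform(X[fold]))
            pooled[fold] = pred_s * sy.std[0] + sy.mean[0]
        if self.log_target:
            pooled = np.expm1(pooled)
        obs = self.endog.to_numpy()
        cv_r2 = r_squared(pooled, obs)
        cv_rmse = float(np.sqrt(np.mean((np.clip(pooled, 0, None) - obs) ** 2)))
        gp, sx, sy = self._fit_gp(X, y, seed, n_restarts)
        return BurnedAreaGPResults(
            model=self, gp_=gp, x_scaler_=sx, y_scaler_=sy,
            cv_r2=cv_r2, cv_rmse=cv_rmse,
            cv_predictions=pd.Series(np.clip(pooled, 0, None), index=self.endog.index),
            seed=seed, cv_folds=cv, cv_scheme=cv_scheme,
        )


@dataclass
class BurnedAreaGPResults:
    """Fitted burned-area process with cross-validated skill."""

    model: BurnedAreaGP
    gp_: GaussianProcessRegressor
    x_scaler_: _Standardizer
    y_scaler_: _Standardizer
    cv_r2: float
    cv_rmse: float
    cv_predictions: pd.Series
    seed: int = 0
    cv_folds: int = 5
    cv_scheme: str = "blocked"
    n_clipped_: int = field(default=0, init=False)

    # -- prediction ----------------------------------------------------------

    def _design(self, scenario) -> np.ndarray:
        names = self.model.predictor_names
        if isinstance(scenario, pd.DataFrame):
            missing = [p for p in names if p not in scenario.columns]
            if missing:
                raise KeyError(f"scenario is missing predictor(s) {missing}")
            return scenario[names].to_numpy(dtype=float)
        X = np.asarray(scenario, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(names):
            raise ValueError(f"expected (n, {len(names)}) array")
        return X

    def predict(self, scenario, clip: bool = True):
        """Predicted annual burned area (km^2) for a scenario predictor table.

        Negative predictions are clipped to zero (with a running count in
        ``n_clipped_``) — clipping applies at prediction time only.
        """
        X = self._design(scenario)
        pred_s = self.gp_.predict(self.x_scaler_.transform(X))
        pred = pred_s * self.y_scaler_.std[0] + self.y_scaler_.mean[0]
        if self.model.log_target:
            pred = np.expm1(pred)
        if clip:
            n_neg = int((pred < 0).sum())
            if n_neg:
                self.n_clipped_ += n_neg
                logger.debug("%s: clipped %d negative predictions", self.model.name, n_neg)
            pred = np.clip(pred, 0.0, None)
        if isinstance(scenario, pd.DataFrame):
            return pd.Series(pred, index=scenario.index, name="ba_km2")
        return pred

    @property
    def fittedvalues(self) -> pd.Series:
        return self.predict(self.model.exog)

    # -- interpretation ------------------------------------------------------

    def shap_importance(self, seed: int | None = None) -> pd.Series:
        """Per-predictor importance, percent of total (sums to 100).

        Mean absolute Shapley value per predictor over the training rows,
        background = training rows, normalized to percentages.
        """
        X = self.model.exog.to_numpy()
        phi = shapley_values(
            lambda A: self.gp_.predict(self.x_scaler_.transform(A)),
            X, background=X, seed=self.seed if seed is None else seed,
        )
        pct = mean_abs_importance_pct(phi, constant_mask=self.x_scaler_.constant)
        return pd.Series(pct, index=self.model.predictor_names, name="importance_pct")

    def partial_dependence(self, predictor: str, grid_points: int = 30,
                           span_sd: float = 2.0) -> pd.Series:
        """Partial dependence of predicted burned area on one predictor.

        PD(v) = mean over training rows of the prediction with ``predictor``
        set to v; the grid spans the training mean +/- ``span_sd`` SD.
        """
        if predictor not in self.model.predictor_names:
            raise KeyError(predictor)
        j = self.model.predictor_names.index(predictor)
        X = self.model.exog.to_numpy()
        mu, sd = X[:, j].mean(), X[:, j].std()
        grid = np.linspace(mu - span_sd * sd, mu + span_sd * sd, grid_points)
        vals = np.empty(grid_points)
        for g, v in enumerate(grid):
            Xg = X.copy()
            Xg[:, j] = v
            vals[g] = float(np.mean(self.predict(Xg, clip=False)))
        return pd.Series(vals, index=pd.Index(grid, name=predictor), name="pd")

    def plot_partial_dependence(self, predictor: str, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        pd_curve = self.partial_dependence(predictor, **kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(pd_curve.index, pd_curve.values)
        ax.set_xlabel(predictor)
        ax.set_ylabel("predicted burned area (km$^2$)")
        ax.set_title(self.model.name)
        return ax

    def summary(self) -> str:
        lines = [
            f"Burned-area GP results: {self.model.name}",
            "=" * 48,
            f"n years:            {len(self.model.endog)}",
            f"predictors:         {', '.join(self.model.predictor_names)}",
            f"kernel:             {self.gp_.kernel_}",
            f"CV ({self.cv_folds}-fold, {self.cv_scheme}) R^2: {self.cv_r2:.3f}",
            f"CV RMSE (km^2):     {self.cv_rmse:.1f}",
            f"log target:         {self.model.log_target}",
        ]
        imp = self.shap_importance()
        lines.append("predictor importance (%): "
                     + ", ".join(f"{k}={v:.1f}" for k, v in imp.items()))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# predictor selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple
    table: pd.DataFrame  # columns: subset, size, cv_r2

    @property
    def best_cv_r2(self) -> float:
        return float(self.table.iloc[0]["cv_r2"])


def select_predictors(X: pd.DataFrame, y, candidates=None, max_subset_size=None,
                      k: int = 5, seed: int = 0, kernel: str = "rbf+linear",
                      n_restarts: int = 1, cv_scheme: str = "blocked",
                      log_target: bool = False, tie_tol: float = 0.01) -> SelectionResult:
    """Exhaustive predictor-subset search scored by k-fold CV R^2.

    All nonempty subsets of ``candidates`` up to ``max_subset_size`` are
    scored. Subsets whose score lies within ``tie_tol`` of the best count as
    ties, broken toward fewer predictors, then lexicographically — a
    parsimony rule in the spirit of the one-standard-error convention, which
    keeps pure-noise predictors from riding in on sub-percent score
    fluctuations. More than 20 candidates requires an explicit
    ``max_subset_size`` cap.
    """
    candidates = list(candidates if candidates is not None else X.columns)
    if not candidates:
        raise ValueError("no candidate predictors")
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidates)} candidates: exhaustive search refused; "
            "cap the candidate list"
        )
    if len(np.asarray(y)) < 5:
        raise ValueError("predictor selection needs >= 5 training years")
    max_subset_size = max_subset_size or len(candidates)
    rows = []
    for size in range(1, max_subset_size + 1):
        for subset in combinations(candidates, size):
            res = BurnedAreaGP(y, X[list(subset)], kernel=kernel,
                               log_target=log_target).fit(
                seed=seed, n_restarts=n_restarts, cv=k, cv_scheme=cv_scheme)
            rows.append({"subset": subset, "size": size, "cv_r2": res.cv_r2})
    table = pd.DataFrame(rows)
    score = table["cv_r2"].fillna(-np.inf)
    best = score.max()
    # within tie_tol of the best: prefer the smallest, then lexicographic
    table["is_tied"] = score >= best - tie_tol
    table = table.sort_values(
        by=["is_tied", "size", "subset"], ascending=[False, True, True]
    ).reset_index(drop=True)
    selected = tuple(table.iloc[0]["subset"])
    table = table.sort_values(by=["cv_r2"], ascending=False).reset_index(drop=True)
    return SelectionResult(selected=selected, table=table.drop(columns="is_tied"))


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccContribution:
    """ACC fraction of predicted burned area with the annual decomposition."""

    fraction_pct: float
    annual_difference: pd.Series  # signed, unclipped
    total_obs: float
    total_nat: float
    undefined: bool = False


def acc_contribution(pred_obs: pd.Series, pred_nat: pd.Series) -> AccContribution:
    """ACC fraction = 100 * sum(pred_obs - pred_nat) / sum(pred_obs).

    Annual differences are returned signed — ACC may reduce predicted burned
    area in individual years even when the total contribution is positive.
    """
    pred_obs = pd.Series(pred_obs)
    pred_nat = pd.Series(pred_nat)
    if not pred_obs.index.equals(pred_nat.index):
        raise ValueError("scenario predictions must share years")
    if (pred_obs < 0).any() or (pred_nat < 0).any():
        raise ValueError("scenario predictions must be nonnegative")
    diff = pred_obs - pred_nat
    total = float(pred_obs.sum())
    if total == 0:
        logger.warning("ACC fraction undefined: observed-scenario total is 0")
        return AccContribution(float("nan"), diff, 0.0, float(pred_nat.sum()), undefined=True)
    return AccContribution(100.0 * float(diff.sum()) / total, diff,
                           total, float(pred_nat.sum()))


def driver_exclusion_experiment(results: BurnedAreaGPResults, observed: pd.DataFrame,
                                signals: dict) -> pd.DataFrame:
    """Per-driver ACC contributions by removing one signal at a time.

    For each selected climate predictor d with an ACC signal, predictions are
    recomputed with only d's signal subtracted from the observed predictors;
    contribution_d = 100 * sum(pred_obs - pred_d_removed) / sum(pred_obs).
    The final rows report the all-drivers-removed total and the additivity
    gap (sum of single-driver contributions minus the joint total), which is
    zero only for a linear response.
    """
    pred_obs = results.predict(observed)
    total = float(pred_obs.sum())
    years = observed.index.get_level_values("year") if isinstance(
        observed.index, pd.MultiIndex) else observed.index
    drivers = [p for p in results.model.predictor_names if p in signals]
    rows = []
    for d in drivers:
        shifted = observed.copy()
        sig = signals[d]
        series = sig.signal if hasattr(sig, "signal") else sig
        shifted[d] = shifted[d].to_numpy() - series.loc[years].to_numpy()
        pred_d = results.predict(shifted)
        contrib = 100.0 * float((pred_obs - pred_d).sum()) / total if total else np.nan
        rows.append({"driver": d, "contribution_pct": contrib})
    all_removed = observed.copy()
    for d in drivers:
        sig = signals[d]
        series = sig.signal if hasattr(sig, "signal") else sig
        all_removed[d] = all_removed[d].to_numpy() - series.loc[years].to_numpy()
    pred_all = results.predict(all_removed)
    joint = 100.0 * float((pred_obs - pred_all).sum()) / total if total else np.nan
    single_sum = sum(r["contribution_pct"] for r in rows)
    rows.append({"driver": "__all__", "contribution_pct": joint})
    rows.append({"driver": "__additivity_gap__", "contribution_pct": single_sum - joint})
    if abs(single_sum - joint) > 1e-9:
        logger.info("driver additivity gap %.3g points (nonlinear response)",
                    single_sum - joint)
    return pd.DataFrame(rows)


def detrend_experiment(X: pd.DataFrame, y, candidates=None, max_subset_size=None,
                       k: int = 5, seed: int = 0, kernel: str = "rbf+linear",
                       select: bool = True, **fit_kw) -> dict:
    """Refit on linearly detrended predictors and target.

    Removes the OLS linear trend (vs. time order) from every column of X and
    from y, reruns selection (optionally) and fitting, and reports the CV R^2
    on raw and detrended data. A drop in R^2 indicates skill that derived
    from coincident long-term trends rather than interannual variability.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if len(y) < 5:
        raise ValueError("detrend experiment needs series length >= 5")
    t = np.arange(len(y), dtype=float)

    def _detrend(v: np.ndarray) -> np.ndarray:
        b, a = np.polyfit(t, v, 1)
        return v - (b * t + a)

    Xd = X.apply(lambda col: _detrend(col.to_numpy()), axis=0)
    yd = pd.Series(_detrend(y.to_numpy()), index=y.index)

    def _score(Xin, yin):
        if select:
            sel = select_predictors(Xin, yin, candidates=candidates,
                                    max_subset_size=max_subset_size, k=k,
                                    seed=seed, kernel=kernel)
            cols = list(sel.selected)
        else:
            cols = list(candidates or Xin.columns)
        res = BurnedAreaGP(yin, Xin[cols], kernel=kernel).fit(seed=seed, cv=k, **fit_kw)
        return res.cv_r2, tuple(cols)

    r2_raw, sel_raw = _score(X, y)
    r2_det, sel_det = _score(Xd, yd)
    return {
        "cv_r2_original": r2_raw,
        "cv_r2_detrended": r2_det,
        "selected_original": sel_raw,
        "selected_detrended": sel_det,
    }
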