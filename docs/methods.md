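# Methods

This note documents the models, numerical choices and known limitations of
`fireattr`. It is the package's own account of its science; every number it
mentions is computed by the test suite or by `scripts/acceptance.py`.

## The attribution chain

**Forced signal.** For each climate variable the anthropogenic (ACC) signal
is estimated from a multi-model ensemble of annual series as

    ACC(v, y) = mean over models m of [ mean(v_m over the 20-y window ending at y)
                                        − mean(v_m over 1921–1940) ]

Departures are *signed*: a negative forced precipitation change is a valid
signal, which a mean of magnitudes could not represent. Differencing each
member against its own reference mean removes constant model biases, so
adding a constant to a member's whole series leaves the signal unchanged (a
tested invariant). The window-to-year assignment is trailing (the signal for
2020 uses 2001–2020) because the constructed series end in 2020; a centered
labeling is available (`labeling="centered"`) for series that extend beyond
the analysis period.

*The low-pass lag.* For a variable trending at rate b, the trailing-window
mean lags the instantaneous forced value by (window−1)/2 ≈ 9.5 years of
trend: the estimand of this method is the window-filtered forced component,
not the instantaneous one. `SyntheticTruth.expected_acc_signal` exposes that
estimand; the ensemble-consistency test (estimate within 2 ensemble standard
errors in ≥90% of seeds) is stated against it, since sampling error cannot
bracket a deterministic filter property. In the attribution itself the lag
means the subtracted signal is slightly smaller than the true forced
departure, so estimated ACC fractions carry a small negative bias — visible
in the recovery tests, which nonetheless bound the per-stratum error at ±10
percentage points. Users analysing a truth whose forcing starts late
relative to the window should expect a proportionally larger lag.

**Counterfactual scenario.** `natural(v, y) = observed(v, y) − ACC(v, y)`,
after which physical bounds are re-imposed (RH ∈ [0, 100]%, precipitation,
VPD, specific humidity ≥ 0) with clip counts logged; before clipping the
reconstruction `observed = natural + signal` is exact. NDVI is passed
through unchanged: its interannual variability is treated as entirely
natural, since the climate models used for the signal carry no dynamic
vegetation. VPD, where not directly available, is computed as
`e_s(T)·(1 − RH/100)` with the Tetens saturation form
`e_s(T) = 0.6108·exp(17.27·T/(T+237.3))` kPa (Magnus variant available).

**Burned-area model.** One Gaussian-process regression per (ecoregion,
ignition source): annual burned area (km²) on standardized ecoregion-mean
predictors, target standardized (optionally log1p for heavy-tailed series).
The default kernel is

    C·RBF(anisotropic) + C·DotProduct + White

The linear (dot-product) term is load-bearing: the counterfactual scenario
shifts predictors one to three standard deviations below the training
envelope, where a pure squared-exponential posterior reverts to its prior
mean and systematically understates the forced response (in side-by-side
runs the pure-RBF kernel biased recovered ACC fractions by roughly −16
percentage points at realistic fraction magnitudes; the composite kernel
removed the bias). Pure "rbf", "matern52" and "linear" kernels remain options —
"linear" doubles as an exact-additivity oracle in tests. Hyperparameters by
marginal-likelihood maximization with restarts (default 5; CV folds use
fewer).

**Cross-validation and skill.** 5-fold CV with contiguous-in-time blocks by
default (less leakage under serial correlation; seeded random folds
available). Standardization constants are computed on training folds only;
out-of-fold predictions are pooled before computing R² and RMSE. R² is the
squared Pearson correlation between predicted and observed annual series
(symmetric, insensitive to calibration); the `1 − SSE/SST` variant is
available where bias should be penalized. Near-constant predictions make a
Pearson correlation numerically meaningless, so R² is NaN (flagged) when
the prediction variance is ~0.

**Predictor selection.** Exhaustive search over all nonempty candidate
subsets (capped at 20 candidates), scored by CV R². Scores within 0.01 of
the best are treated as ties and broken toward fewer predictors, then
lexicographically — a parsimony rule in the spirit of the one-standard-error
convention. Without it, pure-noise predictors ride in on sub-percent score
fluctuations (measured margins in simulation were within ±0.01).

**Attribution.** ACC fraction = `100·Σ(pred_obs − pred_nat)/Σ(pred_obs)`
over the analysis years. Annual differences are kept signed — ACC can reduce
predicted burned area in individual years. Negative predictions are clipped
to zero at prediction time only, never during training. Per-driver
contributions come from removing one variable's signal at a time; the
all-drivers-removed total and the additivity gap (zero only for a linear
response) are reported alongside. Shapley importances use an interventional
value function (absent features marginalized over the training rows),
enumerated exactly for the small predictor counts used here and normalized
to percentages summing to 100. A detrending experiment (OLS-detrend all
predictors and the target, refit) separates skill due to interannual
variability from coincident long-term trends.

**Emissions.** Counterfactual dry matter preserves the observed spatial and
sub-annual pattern of burning and scales each ecoregion-year by
`r = BA_nat_pred / BA_obs_pred`, with predictions summed over ignition
sources (inventory dry matter is not ignition-stratified). `r` is capped
(default 5.0, logged) when the denominator degenerates to zero. Species
emissions: `Σ_type DM · fraction(type) · EF(type, species)/1000` (EF in
g/kg, emissions in kg). The fitted linear DM~BA relation is kept as a
diagnostic only; the scaling uses the pure ratio. Emission factors ship as
an editable config with illustrative literature-scale defaults (forest OC
9.6, BC 0.52; savanna OC 2.6, BC 0.37 g per kg dry matter).

**Smoke and exposure.** `smoke_obs = CTL − BKG`, `smoke_nat = NAT − BKG`,
`ACC = smoke_obs − smoke_nat`, `NV = smoke_nat`; the decomposition is exact
before flooring of tiny numerical negatives (counts logged). OA = 2.1·OC.
Percent-contribution maps divide period-mean components by period-mean total
PM2.5, masked below 0.1 µg m⁻³ to avoid division blow-ups in empty cells.
Trend attribution is the ratio of Theil–Sen slopes (ACC over total) and is
flagged not-meaningful when the total slope is nonpositive; it can also be
numerically unstable when the total slope is near zero, so the
Mann–Kendall significance of the total trend is always reported with it.
Exposure is `Σ c_i p_i / Σ p_i` per region; zero-population regions are NaN
and flagged.

**Trend statistics.** Theil–Sen slope via the all-pairs median
(`scipy.stats.theilslopes`; equal-abscissa pairs are skipped by
construction). Mann–Kendall S with an exact permutation null for n ≤ 10
(inversion-counting DP) and the tie-corrected normal approximation with
continuity correction otherwise. Burned-area slopes are also reported in
σ/decade units (10·slope/SD of the series), undefined (flagged) for a
constant series.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs, not
their geography:

- **Climate ensemble**: member = shared forced component + model offset
  (SD 0.8 native units) + internal variability (white or AR(1)). The forced
  component is piecewise: flat to 1945, then linear, reaching ~1.5 K (Tmax)
  and ~0.15 kPa (VPD) by 2020 — magnitudes of the order reported for the
  recent western-US forced signal. A mid-century onset keeps the reference
  period (1921–1940) genuinely "preindustrial-adjacent" and keeps the
  trailing-window estimand close to the instantaneous forced component.
- **Observed record**: same forced component + one natural realization;
  NDVI stationary.
- **Burned area**: linear (optionally log-linear) response per stratum to
  anomaly-centered Tmax/VPD (+NDVI for human ignitions), multiplied by
  mean-one lognormal noise with log-SD 0.10. The noise level is set so
  cross-validated R² of the fitted models falls in the 0.4–0.9 range
  reported for real ecoregion-scale burned-area regressions; response
  strengths make lightning fires more climate-sensitive than human-ignited
  ones and give true ACC fractions spanning roughly 25–50% across strata.
  Annual totals are disaggregated into records (Dirichlet shares; exact
  conservation by construction) with an additional ~8% of missing-cause
  records that exercise the exclusion filter without entering the truth
  table.
- **Emissions**: ecoregion DM linear in burned area (2×10⁶ kg/km², 10%
  noise) on a fixed spatial pattern shared across scenarios.
- **Transport**: an explicit cell-to-cell Gaussian kernel with columns
  normalized to 1, so domain totals of emitted mass are conserved exactly
  and the smoke ACC share provably equals the emissions ACC share — the
  identity the acceptance tests check to 1e-6. The gain (2×10⁻⁶ µg m⁻³ per
  kg) is calibrated so domain-mean smoke is a sizable fraction of the
  2 µg m⁻³ background, as for fire-season PM2.5 in the western US.
- **Reproducibility**: all draws flow from one master seed through named
  substreams (CRC32 of the stream name into a SeedSequence), so
  regenerating one dataset never perturbs another and identical
  truth + seed gives bit-identical outputs.

What the generator does **not** emulate: real geography and orography, fire
spread and persistence, weather autocorrelation beyond AR(1), seasonality
(annual means only, so the fire-season config toggle is a no-op on synthetic
inputs), transport meteorology (the kernel is static and linear), and any
anthropogenic non-climate driver (suppression policy, land use). Passing
recovery tests therefore demonstrate that the chain's statistics are
implemented correctly and are unbiased under the stated generating process —
not that the method is robust to real-data pathologies such as regime
shifts, nonstationary suppression, or confounded vegetation trends.

## Problem sizes and defaults

Default study: 20×20 grid, 5 contiguous ecoregions (longitude bands), two
ignition sources, analysis years 1992–2020 (29 annual values per stratum),
12 pseudo-models over 1920–2020, window 20 y, reference 1921–1940.
Monte-Carlo tests use 20–50 seeds; recovery tolerances are ±10 percentage
points per stratum (mean over 20 seeds) for the ACC fraction and ±5 points
under a zero-trend null. These sizes keep the full suite and the acceptance
script desk-scale while leaving the statistical checks well-powered.

## Degenerate inputs and tie-breaks

- Constant series: Theil–Sen slope 0, σ-normalized slope NaN + flag.
- Σ pred_obs = 0: ACC fraction NaN + flag, never an exception.
- Zero-variance predictors: standardization uses SD 1, Shapley importance
  exactly 0%.
- 0/0 burned-area ratios: ratio 1 (no fire either way, dry matter kept).
- RH/precipitation bounds re-imposed after subtraction; clip counts logged.
- GP optimizer non-convergence: multiple restarts; sklearn's optimizer
  warnings are suppressed during fits, failures surface as exceptions.

## Design choices that were genuinely open

- **Kernel with a linear term** (above): chosen for extrapolation fidelity
  under the counterfactual shift; config-swappable.
- **Selection score = cross-validated R²**, not in-sample R²: in-sample
  selection trivially prefers the full predictor set.
- **Signed departures** in the forced signal: magnitudes would forbid
  negative (e.g. precipitation) signals.
- **Blocked CV folds** by default: annual series are serially correlated.
- **Pure-ratio emissions scaling** with the fitted DM~BA relation retained
  as a diagnostic: the ratio method is the literal scaling rule; the role of
  a fitted intercept in scaling is ambiguous and therefore avoided.
- **Subtract signals at ecoregion level**: aggregation and subtraction
  commute for linear aggregation, so the order is immaterial (asserted by
  the reconstruction test); ecoregion level avoids regridding noise.
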