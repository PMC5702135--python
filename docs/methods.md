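# Methods

## Model and estimand

Microbial batch growth under non-limiting conditions follows
dc_X/dt = μ·c_X with constant maximum specific growth rate μ (h⁻¹).
`mbgrowth` treats the blanked backscatter signal as proportional to biomass
and estimates μ as the slope of ln c_X versus time over the exponential
window. No conversion to cell dry weight or optical density is attempted —
backscatter-to-biomass calibration is organism specific and out of scope;
rates are reported on the signal scale, which is invariant to a constant
proportionality factor.

## Blank and measurement-error estimation

The backscatter error is modelled as additive and homoscedastic: every
reading carries the same absolute error δ, estimated as the sample standard
deviation of the pre-growth cycles, whose mean is the blank. The default
policy uses the first k = 5 cycles (45 min at the 9-min cycle time —
comfortably inside a typical pre-growth plateau and enough readings for a
usable spread estimate); an adaptive policy instead grows the window while
each next reading stays within blank ± 3δ of the running estimate and
reports a limit of detection LOD = blank + 3δ. The fixed count is the
default because it is reproducible and independent of the (noisy) running
δ; the adaptive mode is useful when lag lengths vary wildly across a plate.

Subtracting the blank, itself a mean of n_pre noisy readings, inflates the
per-point error of the blanked signal to

    δ_cX = sqrt(δ² + δ²/n_pre).

With k = 5 this is 1.095·δ, e.g. δ = 0.36 a.u. propagates to 0.39 a.u. and
δ = 0.31 a.u. to 0.34 a.u. — the per-point error scales used throughout the
synthetic presets.

## Limit of quantification

Rate fitting starts at the first cycle whose blanked value *strictly*
exceeds the user-supplied LOQ. The LOQ is deliberately a user input — it
encodes how much of the noisy low-signal region the analyst is willing to
trust. When omitted, 10·δ is used (the conventional quantification limit)
and flagged in the output. Wells that never cross the LOQ are reported as
non-growers; a plate run continues.

## Exponential-window search

The initial window runs from the LOQ crossing to the final cycle
(typically deep in stationary phase). Each iteration fits a weighted linear
regression to the log-transformed window and evaluates three criteria; if
any fails, the last point is removed:

1. adjusted R² > threshold (default 0.99);
2. last biomass increase strictly greater than the previous one;
3. both increases non-negative.

Criterion 1 alone is insufficient at 9-min resolution: a handful of
stationary points barely dent R². Criterion 2 exploits the convexity of the
exponential on the linear scale; criterion 3 rejects the transient signal
dip often seen at the exponential-to-stationary transition. The increases
are computed on the blanked linear-scale values of the *current* window
(the loop removes the final measurement of the evaluated subset), zero is
allowed for criterion 3 but not 2 — literal readings of "higher than" and
"must not be negative". The minimum window is 4 points (3 for a defensible
regression, one more so both increases lie inside the fitted window); a
window that shrinks below it yields a flagged, non-fatal
"no exponential phase" result. The search touches only the trailing edge,
so it isolates the *first* exponential phase of diauxic curves; second
phases are intentionally not analysed. A perfectly constant window (zero
weighted variance) makes R² undefined; it is treated as a failed iteration.

## Regression

Log-transforming c_X maps the additive error to δ_cX/c_X, so the weighted
fit uses weights (c_X/δ_cX)² — late, large-signal points dominate, which is
statistically correct under the additive model. Slope and intercept come
from the closed-form weighted normal equations in centered coordinates
(numerically stable for ill-scaled time vectors); the slope variance uses
the weighted residual variance with n−2 degrees of freedom, and the 95% CI
a Student-t quantile (the t/normal difference is negligible at the ~60
points of a typical window but t is exact for small windows). Weighted R²
is computed about the weighted mean, so it reduces to the ordinary
definition at equal weights. For an exactly noiseless curve (δ = 0) unit
weights are substituted.

The non-linear route fits c0·e^{μt} to the untransformed signal by
least squares weighted 1/δ_cX² (a toggle disables weighting), seeded by the
linear fit, using a Levenberg–Marquardt minimizer with relative parameter
tolerances of 1e−12 and a 500-iteration budget; the CI derives from the
Gauss–Newton curvature at the optimum with n−2 dof. It exists as a
cross-check: on realistic data both routes agree to ≪1%, and the package
reports the linear fit as the primary rate.

## Synthetic data generator

A simulated well is blank_level + x(t) + ε, ε i.i.d. N(0, noise_sd²), with
latent signal x(t): constant c0 through the lag, c0·e^{μ1(t−t_lag)} during
the first phase, optionally a second exponential phase at μ2 < μ1
(diauxie), capped at a plateau (hard cap by default; a smooth
exponential-approach variant mimics the rounded transition of real
curves). Two presets encode the study conditions the package targets:

- **single-phase** (C. glutamicum-like): μ1 = 0.46 h⁻¹, lag 5 h, plateau
  35 a.u., noise 0.36 a.u., 9-min cycles over 30 h (201 cycles);
- **diauxic** (E. coli-like): μ1 = 0.61 h⁻¹, first phase to 7 h reaching
  ~25 a.u., then μ2 = 0.04 h⁻¹ toward the 35 a.u. plateau, noise 0.31 a.u.,
  24 h.

The noise levels are chosen so a 5-cycle blank window propagates to
per-point errors of 0.39 and 0.34 a.u. respectively; the diauxic first
phase must plausibly reach ~25 a.u. because a shallower phase
(top ≲ 15 a.u. at this noise) cannot support adjusted R² > 0.99 at all and
would contradict the premise that the assay detects these phases. Inoculum
signals (c0 = 0.4–0.5 a.u.) correspond to typical starting densities.
Per-well seeds derive deterministically from a master seed.

What the generator does *not* emulate: multiplicative or drifting noise,
optical crosstalk between wells, morphology-dependent backscatter changes,
rounded lag-to-exponential transitions, or evaporation trends. Passing
tests therefore demonstrate correctness of the estimation machinery under
the additive-noise exponential model, not robustness to every artifact of
real plates.

## Known limitations

- **Inoculum-blanking bias.** Blanking by the pre-growth signal subtracts
  the inoculum's own contribution c0, so the fitted quantity is
  c0·(e^{μt'} − 1), whose log-slope exceeds μ near the LOQ. Under the
  single-phase preset (c0 = 0.5 a.u., LOQ = 4 a.u.) this biases μ̂ upward
  by ~2–3% — invisible per-well but systematic. It is intrinsic to any
  workflow that blanks with the initial value; raising the LOQ or
  inoculating more dilutely reduces it. Recovery tests therefore separate
  statistical accuracy (measured against the rate the blanked latent curve
  actually encodes over the accepted window) from this documented offset.
- Per-well CIs quantify regression uncertainty within the accepted window
  only; window-selection uncertainty and the blanking bias are not
  propagated.
- Organisms with non-exponential kinetics need a differential (rate-over-
  time) analysis; this package will correctly refuse such wells rather than
  fit them, reporting "no exponential phase".
- Replicate aggregation is a plain arithmetic mean with per-replicate CIs
  passed through; no pooled interval is attempted.
- Dissolved-oxygen traces are stored and plotted only; DO-based event
  detection (e.g. glucose-depletion spikes) is out of scope.
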