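# Methods

This note documents the statistical procedure implemented in `seamspc`, its
assumptions, the numerical choices made where the design was open, and what
the synthetic scenarios do and do not establish about real deployments.

## Problem setting

A fixed sensor platform produces one time series per variable, each at its
own cadence, with occasional outages. The monitoring question is
multivariate: a deployment is "in control" when the joint pattern of all
variables matches a calibration period, and the interesting departures are
(a) systematic drift of the whole pattern (environmental trend) and (b) a
single sensor breaking the correlation structure it used to share with its
neighbours (sensor fault). A PCA calibration model separates exactly these
two axes via Hotelling's *T²* (in-model distance) and the *Q*-residual
(off-model distance).

## Alignment

Every stream is linearly interpolated onto a common equally spaced grid
(default 1 h). Choices:

* **Grid anchor** — the first whole multiple of the grid step (measured
  from the epoch, i.e. whole hours on the wall clock for the default step)
  at or after the earliest sample. This makes the grid a deterministic
  function of the data, not of call order.
* **No extrapolation** — cells before a stream's first or after its last
  sample are missing.
* **Gap guard** — a cell whose two bracketing raw samples are more than
  `max_gap` apart (default 6 h) is missing rather than bridged. A grid
  point that coincides exactly with a raw sample always takes that value.
  Increasing `max_gap` can only fill cells in, never create new holes.
* **Row policy** — rows in which *every* variable is missing are dropped;
  they carry no information and would otherwise inflate the grid during
  platform-wide outages. Timestamps are treated as UTC.
* Faster-than-grid streams (5-min data on an hourly grid) are interpolated
  like everything else; the two raw samples bracketing each grid point
  determine its value. No smoothing or averaging over the interval is
  applied — the sampling rate is high relative to the processes of
  interest, so interpolation and nearest-sample assignment differ
  negligibly, and one uniform rule is simpler to reason about.

## Preprocessing and NIPALS

All variables are mean centred and scaled to unit calibration variance
("autoscaling"), with means and standard deviations computed over available
cells only. Variables with zero variance are rejected by name — they cannot
be autoscaled and carry no monitoring information.

Components are extracted one at a time by NIPALS alternating regressions
restricted to observed cells:

```
p_j = Σ_{i∈obs(j)} r_ij t_i / Σ_{i∈obs(j)} t_i²   then  p ← p/‖p‖
t_i = Σ_{j∈obs(i)} r_ij p_j / Σ_{j∈obs(i)} p_j²
```

followed by deflation `R ← R − t pᵀ` on observed cells. Numerical choices:

* **Initialisation** — the residual column with the largest sum of squares.
  Deterministic: the same data always yields the same model.
* **Sign convention** — the largest-magnitude entry of each loading is made
  positive. PCA signs are otherwise arbitrary; sign-sensitive comparisons
  elsewhere use absolute values.
* **Re-orthogonalisation** — each loading iterate is orthogonalised against
  previously extracted loadings, keeping `PᵀP = I` to machine precision
  regardless of how deflation round-off accumulates.
* **Convergence** — relative change of the score vector < `tol`
  (default 1e-10), capped at `max_iter = 5000`. Power-type iterations
  converge linearly at the eigenvalue ratio, so near-tied eigenpairs are
  also accepted once the eigenvalue has been stable to `tol` for several
  iterations while the direction still creeps (any basis of a tied subspace
  is statistically equivalent); genuine non-convergence raises an error
  naming the component. The iteration cap is set generously because a 1%
  eigen-gap legitimately needs a few thousand iterations at 1e-10.
* **Divergence guard** — on some missing patterns the observed-cell
  alternating-least-squares objective is unbounded (a row observed only on
  near-zero loadings gets an arbitrarily large score). The fit aborts with
  an error instead of returning a degenerate component.

Explained variance per component is tracked as the drop in observed-cell
residual sum of squares at each deflation, relative to the preprocessed
total — for complete data this equals the usual `λ_a (n−1) / TSS`.

**Projection** of new observations uses calibration means/scales and solves
least squares over observed loading rows (`t = Pᵀx` for complete rows).
Rows with fewer observed values than components are flagged, not scored.

## Cross-validation of the component count

Segmented cross-validation with **contiguous time blocks** (default 10):
observatory data are serially correlated, so random segments would leak
held-out information through neighbouring timestamps. Each held-out cell is
predicted from the *other* variables of its own row through the refit
loadings (rank-one downdate of the normal equations), so a variable never
predicts itself. Validated variance is `1 − PRESS/TSS` cumulatively; the
suggested dimensionality is the last component whose validated-variance
increment exceeds one percentage point (configurable). Rank-deficient
refits (noiseless low-rank data) fall back to as many components as exist.

## Multi-block structure

Wide blocks would dominate a flat PCA by column count alone (here, 78
current variables against 10 individual sensors). Each declared block is
therefore summarised by its own autoscaled PCA (default 3 components) and
its calibration score vectors enter the super model as new variables next
to the individual sensors. The super-matrix is **autoscaled again**, so
every super-variable — sensor or block score — carries unit calibration
variance; without this the block-score columns would enter with their raw
score variances and the λ-ordering would weight blocks unequally.

End-to-end projection runs raw block variables through their sub-model
(missing-aware) and the assembled super-vector through the super model.
*T²*/*Q* and their limits are evaluated at the super level — one chart for
the whole deployment — while block-level *Q* is computed and retained for
drill-down. An observation missing an entire block is flagged, not scored.

## Control limits and classification

* ***T²* limit** — `A(n−1)(n+1)/(n(n−A)) · F₁₋α(A, n−A)`, the limit for an
  observation *not* used in calibration.
* ***Q* limit** — Jackson–Mudholkar, from the moments θ₁, θ₂, θ₃ of the
  calibration residual eigenvalues (all eigenvalues above machine-precision
  relative threshold), with a `g·χ²_h` moment-matching fallback when
  h₀ ≤ 0.
* **α** defaults to 0.05 and is configurable; the warning threshold is 0.8
  of the critical limit by default.
* **Missing data at monitoring time** — *Q* is summed over observed cells
  only while the limit is left unadjusted (conservative); affected rows are
  flagged `has_missing` in the output.
* ***T²* contributions** use the score-weighted decomposition
  `c_j = Σ_a (t_a/λ_a) p_aj z_j`, chosen among the published variants
  because it sums exactly to *T²* and yields one bar per variable.

Coverage caveat: with a finite calibration set the limits are themselves
estimates, so the realised false-alarm rate fluctuates around α from one
calibration to another (at n = 500 and α = 0.05, roughly ±0.005–0.01).
The Monte-Carlo checks in the test suite and acceptance script quantify
this at 10⁴ monitored observations.

## Sensor diagnostics

* **Redundancy** — pairwise Pearson correlation over jointly observed raw
  values within declared groups (≥ 30 joint points required). Only a
  correlation below the threshold (default 0.7) flags; the mean offset is
  reported but benign — two healthy thermometers can disagree by a constant
  while tracking the same water mass.
* **Saturation** — a mis-ranged sensor pegs at its ceiling. The detector is
  signature-based, not value-based (the true ceiling is never known in
  advance): flag when one rounded value (3 significant digits, the typical
  sensor resolution) holds more than 50% of observations *and* is the
  variable's maximum. Flat-lines at the floor or mid-range are left to the
  correlation checks. Operates on raw, pre-scaling values.
* **Missing alert** — variables exceeding 10% missing cells are listed;
  they are retained in models unless the user excludes them.

## Synthetic scenarios

The generator emulates the covariance and trend structure the statistics
operate on, not ocean physics. The default deployment (all values chosen
once, as plausible magnitudes for a summer shelf deployment):

* 3.5 months (May 16 – Aug 31), with sensor cadences of 5 min
  (temperature/conductivity/turbidity), 10 min (both current profilers and
  their temperatures) and 1 h (chlorophyll, biomass).
* A seasonal latent trend (ramp plus slow wiggle, unit variance) driving
  three offset thermometers (loading 1.5 temperature units over the record,
  noise sd 0.05 — redundancy r ≈ 0.999), conductivity and salinity with
  proportionally smaller loadings.
* Two stationary current-forcing factors (east, north; Gaussian-smoothed
  noise with ~6 h correlation time), expressed at 9 Aquadopp depths
  (3–23 m) and 30 Continental depths (8–153 m) through a linear
  depth-attenuation gradient, stronger eastward (amplitudes 1.0 vs 0.6).
  Overlapping depths (8/13/18/23 m) observe the same factors, so
  cross-profiler redundancy is high (r ≈ 0.8–0.93) but below within-profiler
  redundancy, because each profiler+direction also carries an
  instrument-common noise component (sd 0.10) on top of per-bin noise
  (sd 0.08).
* A biomass factor (12 h correlation) behind three echo-sounder bands and
  chlorophyll; turbidity is almost pure noise (trend loading 0.03) —
  deliberately the "poorly explained variable" case.
* Sporadic missingness: per-sample dropout (rate 0.001) plus rare
  per-stream outages (0.3 expected per stream, 7–24 h), which is what
  produces actual missing cells after hourly alignment.

Anomalies are injected from an onset with magnitudes in units of the
target's pre-onset standard deviation; decorrelation replaces the signal
with matched-moment noise, saturation clips at a pre-onset quantile.
Ground-truth latents, loadings and affected-cell masks are returned for
recovery and power studies.

**What passing tests show** — that the implementation is numerically
correct (oracle equivalences, algebraic identities), that the limits hold
their nominal level under the model's own assumptions (Gaussian factors and
noise, linear loadings), and that realistic fault magnitudes are detected
with high power. **What they do not show** — robustness to heavy-tailed
noise, nonlinear or lagged dependencies, tidal or other periodic structure,
and seasonal non-stationarity beyond a monotone trend; real deployments
need season-specific or periodically recalibrated models, which is out of
scope here (limits are fixed at calibration time; no recursive updating).

## Problem sizes

Tests run on one-to-ten-week scenarios (hundreds to ~2000 hourly rows, 88
variables), the Monte-Carlo coverage check on 500 calibration + 10⁴
monitored observations in 12 dimensions, and subspace recovery at n ≈ 2000;
the acceptance script uses the full 3.5-month default scenario. These sizes
give sub-percent Monte-Carlo error on the quantities checked while keeping
any single check in seconds.

## Known limitations

* The observed-cell ALS treatment of missing data is the classical NIPALS
  one; it is reliable for sporadic missingness but can be unidentified for
  adversarial missing patterns (the fit then errors out deliberately).
* The *Q* limit assumes approximately Gaussian residuals; heavy tails
  inflate the false-alarm rate.
* Contribution plots attribute, they do not test; a large contribution is a
  pointer for drill-down, not a significance statement.
* Serial correlation is respected in cross-validation segmentation but not
  modelled in the limits; alarm *runs* are therefore correlated, and event
  counts should be read accordingly.
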