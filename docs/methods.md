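# Methods

This note records the models, parameter choices and numerical decisions
behind `pumppass`, and what the synthetic-data tests do and do not
demonstrate about field data.

## Pressure-trace model and landmark detection

A deployment is modelled as three synchronized pressure channels on a
uniform 100 Hz grid (hPa). Channels whose mean pressure reaches 1e5 hPa are
railed/failed sensors and are dropped before averaging; all downstream
detection runs on the channel average.

Landmarks and parameters, with defaults:

| quantity | rule | default |
|---|---|---|
| injection | first reading above threshold | 1005 hPa |
| pump nadir window | relative to injection | 3–75 s |
| control nadir window | relative to injection | 5–75 s |
| smoothing | Savitzky–Golay | order 2, window 11 samples |
| nadir candidate rule | abs. smoothed change within < 0.1 s | > 20 hPa |
| ROC window | around the nadir | ± 0.5 s |
| acclimation pressure | LRP reference | 1000 hPa |

The pump-passage nadir is the lowest smoothed value among candidate samples;
the change criterion is read literally as: sample *i* qualifies if
`|sp(i) − sp(i − k)| > 20 hPa` for any lag `k/fs < 0.1 s` (both endpoints of
a qualifying change are candidates). Control drifts have no impeller
transient, so no smoothing is applied and the raw window minimum is taken.

**Exit time.** Regions of interest are traditionally marked by eye. For
reproducibility the package detects the exit automatically: the terminal
plateau level is the median of the last 1 s of the smoothed series, and the
exit is the first post-nadir time from which the series stays within
± 5 hPa of that level for 1 s. A manual exit time in the deployment
metadata always overrides the heuristic. A monotonically drifting tail has
no plateau and is reported as an error rather than guessed.

**ROC.** No closed-form definition of the "maximal rate of pressure change"
is fixed by the data themselves; the package reports the maximum absolute
one-sample rate `|ΔP|·fs` of the smoothed series within nadir ± 0.5 s. The
window is configurable; the value is reported in hPa/s and is 0 for a
constant series. Smoothing happens after channel averaging.

**LRP.** `LRP = ln(acclimation / nadir)`, natural log. This is the only
monotone log-ratio convention consistent with ensemble tables in which the
mean LRP exceeds the LRP of the mean nadir — a direct consequence of
Jensen's inequality applied to the convex map `n ↦ ln(1000/n)`, and a
property the test suite asserts on every non-degenerate batch.

**Normalized profiles.** Because the injection→nadir→exit durations differ
between deployments, profiles are landmark-registered onto `u ∈ [0, 1]`
with the nadir pinned at `u = 0.5`: 500 equally spaced points per
half-interval plus the injection endpoint (1001 points), linear
interpolation in between. The registered profile is invariant to uniform
time rescaling of the input. The midpoint is set to the detected nadir
value (which comes from the smoothed series) rather than re-interpolated
from the raw series.

Ensemble tables report mean ± SD (sample SD, ddof = 1) per scenario; a
single-deployment scenario reports SD as not-available rather than 0, to
avoid implying precision.

## Strain-rate estimation

Lateral differentials `ΔP_cl = |P_c − P_l|`, `ΔP_cr = |P_c − P_r|`
(magnitudes — the injury threshold compares against strain magnitude) are
converted with

    ε ≈ 40 ΔP / (μ √Re),    Re = ρ v L / μ

where μ and ρ are dynamic viscosity and density of water at the deployment
temperature and `v` is the assumed passage velocity (default 5 m/s,
precautionary: of the plausible 5–15 m/s range, the lowest velocity yields
the highest strain estimates).

The unit system behind the reported threshold anchors cannot be recovered
from first principles with any physically obvious characteristic length, so
`L` is treated as an *effective* constant fixed by single-point calibration:
`L` is chosen so that ΔP = 3.45 hPa maps exactly onto ε = 500 s⁻¹ at
v = 5 m/s and 4.5 °C. (The resulting `L` ≈ 100 m is not a sensor dimension
and is not interpreted as one.) The calibrated equation then forces the
threshold differential to scale exactly as √v: 4.879 hPa at 10 m/s and
5.976 hPa at 15 m/s. The corresponding reported anchor values, 4.86 and
5.95 hPa, agree with the √v law only to ≈ 0.4–0.5% (their implied velocity
exponent is ≈ 0.495, and no single multiplicative constant reproduces all
three published values to ± 0.01 hPa), so exact agreement at the printed
precision is not attainable from any calibration consistent with the
equation; the package keeps the single 5 m/s anchor and the exact law.

Viscosity uses a Vogel-type correlation
`μ(T) = 2.414e-5 · 10^(247.8/(T_K − 140))` Pa·s (0–40 °C; 1.00e-3 Pa·s at
20 °C, within 2% of handbook values at 4.5 °C); density uses the Kell
polynomial. Temperature enters both the prefactor and Re.

Threshold exceedance integrates the time the pointwise mean of the left and
right strain series spends above 500 s⁻¹, locating crossings by linear
interpolation between samples (agreement with a 10× resampled oracle within
one sample period is asserted). Averaging left/right happens *before*
thresholding. Mean and maximum strain are reported over the
impeller-passage window, taken as nadir ± 0.5 s when marks are available.

## Fish coding

Injury codes are strings from the fixed NEN-style list (1, 2.1–2.3,
3.1–3.7). Class = most severe class present; the "worst code" is the
highest numeric code within that class (ties cannot occur; all codes are
retained for the distribution tables, so no information is lost to the
tie-break). Dead = condition dead/dying, class 3 (severely injured fish are
euthanized), or a delayed-mortality flag; delayed mortality folds into the
single final survival state (no time-to-event modelling). Decapitated or
otherwise non-intact fish are counted but carry no length/mass and are
excluded from length-dependent models by the NA-handling of those models,
not by the outlier filter. Length outliers use fences at Q1 − 3·IQR and
Q3 + 3·IQR per species with the linear-interpolation quantile convention
(configurable); the filter is idempotent on typical data but, like any
quantile-based refence rule, is not idempotent by construction.

Recapture accounting keys start counts by the *theoretical* (release)
scenario and end counts by the *observed* scenario, which is exactly what
lets a scenario fed by lingerers from the previous trial exceed 100%.

## Statistics layer

- **Stepwise AIC** searches bidirectionally from the full model, never
  breaking marginality (an interaction is only kept while both main effects
  are present); the selected AIC is never above the full or null model's.
  Under a null generator this retains a useless 1-df term with asymptotic
  probability P(χ²₁ > 2) ≈ 0.16 — that is a property of AIC selection, not
  a defect, and the tests assert rates consistent with it.
- **Logistic survival models** are Bernoulli GLMs per species (rpm
  discrete, length continuous and centered, optional interaction). Strata
  with a single outcome (e.g. 100% survival) are excluded before fitting —
  their coefficients and standard errors diverge — and are reported on the
  results object. Scenario predictions with 95% bands are evaluated at a
  reference length (species mean by default) using the asymptotic
  covariance on the link scale, back-transformed.
- **Random-intercept check.** Release samples introduce a possible grouping
  effect. No installed Python package provides a frequentist
  random-intercept logistic GLMM, so the package fits one directly by
  Gauss–Hermite quadrature (21 nodes) over a scalar intercept SD, started
  from the GLM fit. Samples with fewer than 6 fish are not used. If the
  fitted SD is below 0.01 on the logit scale the fit is singular and plain
  logistic models are recommended.
- **Trees** are CART (Gini) with min 20 records per split and
  cost-complexity pruning (α = 0.01) — conservative settings chosen because
  the scientifically meaningful trees in this setting are small; when no
  split survives, the result is an explicitly labelled "no tree" root.
  Categorical predictors are one-hot encoded; node labels use the 50% dead
  rule; child coverages sum exactly to the parent's.
- **Multinomial injury models** use the no-injury class as reference (the
  reported per-category probabilities do not depend on that choice);
  probability bands come from the delta method with a numerical Jacobian on
  the per-equation parameter covariance. Predicted probabilities sum to 1
  to 1e-9 at any covariate value.
- **Nonparametric sensor tests**: Kruskal–Wallis omnibus; only when it
  rejects, pairwise two-sample Wilcoxon rank-sum tests with Bonferroni
  correction `min(1, m·p)` over the m pairs actually tested. The rank-sum
  (not signed-rank) flavour is deliberate: deployments are unpaired across
  scenarios. Identical samples short-circuit to p = 1 rather than relying
  on tie handling. Stars: ns (> 0.05), * (0.05–0.01), ** (0.01–0.001),
  *** (0.001–0.0001), **** (< 0.0001); no multiplicity correction is
  applied across the many per-species models.

## Synthetic data: what it emulates, and what it does not

Pump traces: in-air baseline 1000 hPa, +35 hPa hydrostatic step at
injection, a single Gaussian dip at the impeller, settling to the tailwater
plateau at exit; three channels share the mean signal plus independent
Gaussian noise (default SD 1.0 hPa — the sensors' field accuracy) plus an
asymmetric lateral differential pulse near the nadir. Default dip depth is
80 hPa (a typical fish-friendly-pump nadir below the in-water baseline).

The default dip half-width is σ = 70 ms. A 50 ms dip was considered (total
visible dip ≈ 0.3 s), but the order-2/window-11 smoother attenuates the
minimum of a σ = 50 ms dip by ≈ 1.2% of its depth (derived from the filter's
center weights), i.e. ≈ 1 hPa per 80 hPa of dip — larger than the sensor
accuracy and large enough to dominate the nadir-recovery error budget. At
σ = 70 ms the attenuation drops to ≈ 0.34% of depth while the dip remains
sub-second and the 20 hPa / 0.1 s change criterion still fires for depths
above roughly 35–40 hPa; the batch generator therefore truncates drawn dip
depths at 40 hPa, and its per-scenario nadir SD (25 hPa) keeps that
truncation ≈ 2.5 SD into the tail so ensemble means stay on target.

Cohorts: Gaussian lengths per species (roach 168 ± 20 mm, bream
374 ± 40 mm, eel 635 ± 60 mm), survival from a logistic in centered length,
rotation speed and pump type, injury codes drawn conditional on the
survival class, near-injury-free controls, a configurable lingering
fraction and a recapture-loss fraction. Default coefficients reproduce the
qualitative ordering eel ≈ 100% > roach > bream and conventional pump below
the fish-friendly pump; the magnitudes are configuration, not claims.

Not emulated: non-Gaussian sensor noise and dropouts, multiple dips from
recirculation, depth-dependent hydrostatic ramps, sensor-to-sensor clock
skew, fish behaviour (avoidance, delayed passage correlated with
condition), species beyond the three modelled, and any hydrodynamic
structure inside the pump (no CFD). Passing tests therefore demonstrate the
*correctness of the processing and inference machinery under the stated
generative assumptions*, not field validity of the biological rates.

## Numerical conventions and degenerate inputs

All pressures are hPa end-to-end; sampling rate from metadata (default
100 Hz); seeds are explicit everywhere and all generators are
seed-deterministic. Errors are typed (e.g. all-channels-invalid, no
injection, no nadir, no exit, unknown injury code, missing start count,
missing scenario level) rather than silent NaNs. Empty candidate sets,
windows extending past the trace end, and single-sample ROC windows
degrade to defined results (error, clipped window, 0 respectively).

Test problem sizes were chosen to keep the default suite fast while leaving
sampling error well below the asserted tolerances: 200 traces for detection
recovery, 400–500 replicates for coverage/type-I calibration, cohorts of
~2000 fish, and a 400-deployment batch for the ensemble-mean contract.

## Known limitations

- The exit heuristic assumes the tailwater plateau is reached within the
  record and is stable for ≥ 1 s; surface bobbing larger than ± 5 hPa
  defeats it (use the manual override).
- The strain conversion inherits the calibrated-constant caveat above; only
  the √v scaling and the anchor itself are first-principles checkable.
- Field data arrive as vendor binary files; the package reads the CSV
  dialect documented in `pumppass.io` and leaves binary decoding to an
  upstream adapter.
- Tree split points and per-fish model coefficients are data-dependent;
  with synthetic cohorts only their qualitative structure is reproducible.
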