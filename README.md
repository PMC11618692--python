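# pumppass

Fish-friendliness assessment of axial flow pumps: a tested, reusable pipeline
for processing barotrauma-sensor pressure traces, estimating shear-strain
exposure, coding fish injury/survival observations to the NEN 8775 scheme,
and fitting the cohort statistics that turn both into a verdict on a pump.

## Who this is for

Ecohydraulics and fish-passage researchers evaluating pumping stations with
(a) neutrally buoyant barotrauma detection sensors (BDS) that log total water
pressure on three channels at 100 Hz during pump passage, and (b) cohorts of
live fish (e.g. eel, roach, bream) released through the pump and recaptured,
with standardized injury scoring and 24/48 h delayed-mortality checks. The
package processes both data streams end-to-end and ships a synthetic-data
generator with known latent truth, so every stage is testable without a
field campaign.

## The quantities at the core

For each sensor deployment, from the channel-averaged pressure `P(t)`:

- **Nadir** — minimum total pressure during passage (hPa), reached at the
  impeller. Pump-passage detection: search 3–75 s after injection (first
  reading > 1005 hPa) on a Savitzky–Golay smoothed series (order 2, window
  11), keeping samples whose smoothed pressure changes by more than 20 hPa
  within 0.1 s; controls take the raw minimum 5–75 s after injection.
- **LRP** — log ratio pressure change, `LRP = ln(P_acclimation / P_nadir)`
  with `P_acclimation = 1000 hPa`. A decompression-severity proxy.
- **ROC** — maximal `|dP/dt|` (hPa/s) near the nadir; decompression speed.
- **Shear strain rate** — from the lateral channel differentials
  `ΔP_cl = |P_center − P_left|`, `ΔP_cr = |P_center − P_right|` via
  `ε ≈ 40 ΔP / (μ √Re)` with `Re = ρ v L / μ`; the effective length `L` is
  calibrated once so that ΔP = 3.45 hPa ↔ ε = 500 s⁻¹ at v = 5 m/s, 4.5 °C,
  and durations above the 500 s⁻¹ injury threshold are integrated with
  linear interpolation at the crossings.

Fish records are coded by the rules: injury class = most severe class
observed; dead = observed dead/dying, alive with a severe (class 3) injury,
or delayed mortality at 24/48 h; fish are analysed under the scenario at
which they were observed (lingerers can push a scenario's recapture above
100%); per-species lengths outside `[Q1 − 3·IQR, Q3 + 3·IQR]` are dropped.
The statistics layer provides length ANOVA + Tukey, CART survival trees,
per-species stepwise-AIC logistic survival models (with complete-separation
strata excluded and a random-intercept singular-fit check), multinomial
injury models, a three-scenario pump comparison, and Kruskal–Wallis +
Bonferroni rank-sum tests on the sensor parameters.

## Worked example

```python
import numpy as np
from pumppass import coding, models, signal, strain, synth

# one synthetic pump passage with known ground truth
trace, truth_marks = synth.gen_pressure_trace(synth.TraceScenario(seed=7))
result = signal.PassageModel(trace).fit()
print(result.summary())

ctx = strain.calibrate_char_length()           # fixes L from the 5 m/s anchor
series = strain.strain_series(trace, ctx)
summary = strain.threshold_exceedance(series.eps_mean, trace.meta.fs,
                                      marks=result.params.marks)
print(f"duration above 500/s: {summary.duration_above:.2f} s")

# a synthetic cohort, coded and modelled
records, truth = synth.gen_fish_cohort(
    synth.CohortScenario(seed=11, lingering_prob=0.15))
coded = coding.code_records(coding.reassign_scenarios(records))
coded, n_removed = coding.remove_length_outliers(coded)
print(models.SurvivalLogitModel.from_records(coded, "bream").fit().summary())
```

prints

```
Passage summary
===============
scenario       : FNAFP_468 (sensor SYN-7)
t_injection    :     5.00 s
t_nadir        :    25.00 s
t_exit         :    39.97 s
nadir          :    954.2 hPa
LRP            :   0.0468 (-)
ROC            :    698.3 hPa/s
duration above 500/s: 0.08 s
Logistic survival model — bream
selected terms: ['C(rpm)', 'length_c']
AIC = 196.21
                   coef        se         p stars
Intercept     -1.011418  0.219150  0.000004  ****
C(rpm)[T.550] -0.675483  0.388941  0.082435    ns
length_c      -0.014150  0.004466  0.001533    **

Scenario predictions (at reference length 377 mm):
 scenario   n  survival     lo95     hi95
FNAFP_468 115  0.266702 0.191399 0.358498
FNAFP_550  70  0.156184 0.088504 0.260810
```

Reading it: the detected injection/nadir/exit landmarks match the
generator's truth (5 s / 25 s / 40 s); the 954 hPa nadir gives
LRP = ln(1000/954) ≈ 0.047; the mean strain rate exceeded the 500 s⁻¹
injury threshold for 0.08 s around the impeller. In the cohort, the AIC
search kept both the rotation-speed and length terms: larger bream fare
worse (negative length coefficient) and predicted survival at the average
length drops from 27% at 468 rpm to 16% at 550 rpm, with 95% bands.

There is also an umbrella CLI mirroring the library
(`pumppass {simulate, bds-process, strain, fish-code, fit, report}`; see
`pumppass --help` and `pumppass print-config`).

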