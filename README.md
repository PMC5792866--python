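# movebreak

Detecting and timing behavioural responses of tagged marine animals to
acute disturbances — capture/tagging and short, high-intensity underwater
noise — from high-resolution biologging data: GPS surfacing positions and
1 Hz time–depth records.

The package is written for movement ecologists running controlled exposure
experiments on small cetaceans (the defaults are calibrated for harbour
porpoises and a small airgun), but the statistical core applies to any
setting where a behavioural time series is expected to shift abruptly at a
known disturbance time and to recover gradually afterwards.

## The method

For each individual and each movement parameter — step length (m), speed
(m/s) and absolute turning angle (0–180°) from the screened GPS track;
dive duration (s), maximum dive depth (m), bottom-phase wiggliness (m) and
post-dive surface duration (s) from the depth record — the pipeline:

1. **Removes natural variation.** The parameter is regressed on local hour
   of the day with a cyclic smoother, m(h) = a₀ + Σⱼ [aⱼ cos(2πjh/24) +
   bⱼ sin(2πjh/24)], the number of harmonics chosen by generalized
   cross-validation and the coefficients re-estimated by feasible GLS under
   an AR(1) error process. The raw residuals (data − m(hour)) measure
   deviation from the individual's baseline; a residual of 0 is
   undisturbed behaviour.
2. **Averages residuals into hourly bins** (the finest scale that avoids
   gaps from intermittent GPS fixes, and a further dilution of serial
   correlation).
3. **Fits continuous piecewise linear regressions** of the hourly residuals
   on time since release with k = 0…6 breakpoints ψ₁ < … < ψ_k, using the
   iterative linearization of broken-line models, and ranks the fits by
   AICc (parameter count 3 + 2k). Breakpoints are validated by t-tests of
   the adjacent segment slopes against zero, and their uncertainty is
   quantified by a case-resampling bootstrap (B = 50, percentile 95% CIs).
4. **Classifies the validated breakpoints**: the first one times the
   recovery from capture/tagging; a breakpoint coinciding with the noise
   exposure (within ±2 h, or covered by its CI) marks a noise-induced
   response whose duration and recovery run to the following breakpoints.
5. **Estimates the received noise level** at the animal from the GPS fix
   nearest in time to the exposure: received = source − 17·log₁₀(range in
   metres), for peak-to-peak level (L_pp, 216 dB re 1 µPa at 1 m), 125-ms
   RMS level (L_eq-fast, 195 dB) and sound exposure level (SEL, 186 dB
   re 1 µPa²s), with a ±50 % range error band.

A synthetic-data generator produces GPS tracks and 1 Hz depth series with
known diel structure, AR(1) noise and injected capture/noise responses, so
the whole pipeline can be validated against ground truth.

## Worked example

Received levels for four individuals exposed at 690, 610, 420 and 550 m:

```python
from movebreak import exposure_table
print(exposure_table({"ID1": 690, "ID2": 610, "ID3": 420, "ID4": 550}))
```

```
 id  range_m  L_pp_mean_dB  L_eq_fast_mean_dB  SEL_mean_dB  SEL_min_dB  SEL_max_dB
ID1      690           168                147          138         135         143
ID2      610           169                148          139         136         144
ID3      420           171                150          141         138         147
ID4      550           169                148          139         136         145
```

The mean received SEL at 420 m is 141 dB re 1 µPa²s; across all four
individuals' 50 %-error range bounds the SEL spans 135–147 dB re 1 µPa²s.

Breakpoint detection on hourly residuals containing a capture response
(offset +5 at release decaying to zero by 18 h) and a noise response
(rising to +2 between the 96 h exposure and 102 h, back to baseline at
126 h), with noise of SD 0.05:

```python
import numpy as np
from movebreak import (rank_models, validate_breakpoints,
                       bootstrap_breakpoints, classify, DisturbanceTimes)

hours = np.arange(240.0) + 0.5
psi, slopes = [18, 96, 102, 126], [-5/18, 0, 2/6, -2/24, 0]
resid = 5.0 + slopes[0] * hours
for j, p in enumerate(psi):
    resid += (slopes[j+1] - slopes[j]) * np.clip(hours - p, 0, None)
resid += np.random.default_rng(0).normal(0, 0.05, hours.size)

ranking = rank_models(hours, resid, kmax=6)
fit = ranking.selected
val = validate_breakpoints(fit)
ests = bootstrap_breakpoints(hours, resid, fit.k, B=50, seed=0, fit=fit)
for e, ok in zip(ests, val.accepted):
    e.validated = bool(ok)
summary = classify(ests, DisturbanceTimes(exposure_h=96.0))
```

```
selected k = 5
  breakpoint   17.8 h   95% CI [  17.6,   17.9]   validated=True
  breakpoint   96.2 h   95% CI [  95.7,   96.3]   validated=True
  breakpoint  101.9 h   95% CI [ 101.8,  102.4]   validated=True
  breakpoint  126.3 h   95% CI [ 126.0,  126.6]   validated=True
  breakpoint  227.0 h   95% CI [ 224.8,  237.2]   validated=True
  capture_recovery_h: 17.8
  noise_response: True
  noise_onset_h: 96.2
  noise_response_h: 5.8
  noise_recovery_h: 24.4
```

The four injected breakpoints are recovered to within 0.3 h, the capture
recovery is timed at 17.8 h (truth 18 h), the onset breakpoint coincides
with the exposure, and the response/recovery durations (5.8 h / 24.4 h)
match the injected 6 h / 24 h. The fifth, spurious late breakpoint is
reported among the *unrelated* behavioural changes — exactly how
breakpoints far from either disturbance are treated.

## Command line

```bash
movebreak simulate --seed 3 --out-dir sim      # synthetic track + depth + truth
movebreak screen   sim/track.csv               # positional outlier removal
movebreak steps    track_screened.csv          # step length / speed / turning angle
movebreak dives    sim/depth.csv               # the four dive parameters
movebreak baseline speed_series.csv            # diel fit + hourly residuals
movebreak breakpoints hourly_residuals.csv     # AICc ranking + bootstrap CIs
movebreak classify breakpoints.json --exposure-h 96
movebreak exposure --range-m 420 --range-m 690 # received-level table
movebreak run-all  --config run.yaml           # whole pipeline, one individual
movebreak recover  --seed 4                    # simulate → analyse → compare to truth
```

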