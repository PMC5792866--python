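# Methods

This note documents the models and procedures implemented in `movebreak`,
the assumptions behind them, the numerical choices that were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Movement parameters

**Horizontal.** GPS fixes (one attempt per surfacing, roughly one success
in four) are screened for positional outliers with an impossible-movement
rule: a fix is removed when the incoming step implies a speed above
15 km/h *and* the track returns essentially to its origin in the next move,
operationalised as dist(i−1, i+1) < max(100 m, 10 % of the excursion).
Screening is repeated until no fix qualifies, because one spike can mask
another. The return radius needs a floor (GPS jitter), but the floor has a
side effect worth knowing: when genuine steps are shorter than the floor —
dense sampling of a slow animal — any fast fix looks like an out-and-back
spike. At realistic fix rates (gaps of minutes, steps of hundreds of
metres) the floor is not binding; with every surfacing retained and
baseline speeds near 1 m/s it is, and the screen then clips genuine
post-disturbance bursts. The threshold, fraction and floor are all
parameters.

Distances are great circles on a sphere of radius 6371 km; bearings use
the initial-bearing convention. At the step lengths involved the
difference from an ellipsoidal treatment is far below GPS error. From
consecutive fixes we take step length (m), speed (m/s, length over elapsed
time) and the absolute turning angle (|change in bearing| folded into
0–180°; 0 = directed movement). Displacement from the release and exposure
sites and 10 h windowed net-movement headings are computed as diagnostics
only.

**Vertical.** A dive is a maximal run of 1 Hz depth samples at or below
−2 m lasting at least 5 s (both configurable; the bottom of the literature
offers no canonical values). The bottom phase is the contiguous window
from the first to the last sample at ≥ 80 % of the dive's maximum depth —
a common convention, configurable. Wiggliness is the summed absolute
vertical displacement within that window, a standard proxy for prey
chasing. Post-dive duration is the surface gap to the next dive. Sampling
gaps over 5 s split the record, and dives truncated by a gap are dropped
rather than patched. No zero-offset correction is applied by default —
transducer drift over deployments of a few days is negligible — but a
linear-drift corrector is available. Dive counts are monotone in the
threshold/minimum-duration knobs only for unimodal dive shapes; raising
the threshold can split a multi-lobed excursion into several dives.

## Diel baseline

Each parameter, per individual, is regressed on local hour of day with a
truncated Fourier (harmonic) basis of k harmonics, k = 0…6 selected by
GCV(k) = n·RSS/(n − p)² with p = 2k + 1. The basis is exactly 24 h
periodic with matching derivatives at midnight, so cyclic continuity holds
by construction. This is a deliberate substitute for a penalized cyclic
spline: functionally an equivalent cyclic smoother, with no claim of
numerical equality to spline-based tooling.

Serial correlation at the observation (step/dive) scale is handled by
iterative Prais–Winsten feasible GLS with an AR(1) coefficient φ estimated
from the lag-1 autocorrelation of the raw residuals, iterated to
|Δφ| < 10⁻⁴. Two caveats are documented rather than hidden. First, the
reported residuals are always raw (data − fitted), so under GLS their mean
is not exactly zero. Second, when a strong sustained disturbance response
is present, it dominates the residual autocorrelation and pushes φ toward
1; the GLS fit then behaves like a fit to differenced data. Empirically
this barely moves the fitted diel curve (breakpoint estimates with and
without AR(1) agree to a fraction of an hour on simulated data), but φ
itself should not be interpreted as the true observation-scale coefficient
when responses are present.

Because the smoother is fitted to the *complete* record, disturbance
periods contaminate the baseline: a 30 h response in a 10-day record
inflates m(hour) at the local hours it covers by roughly (response mean) ×
(response span / record length). The residuals therefore carry a small
opposite-signed imprint at those hours on undisturbed days, and breakpoint
onsets can be biased early by a few hours. Fitting the baseline only to
pre-disturbance data would remove this at the cost of a much shorter
training window; with ≤ 12-day records we follow the full-record
convention.

Residuals are averaged within half-open hourly bins [h, h+1) since
release; empty hours are gaps, never zeros.

## Broken-line model of the hourly residuals

The response model is a continuous piecewise linear function of time since
release with k breakpoints, fitted by iterative linearization: given
working breakpoints ψ, regress y on [1, x, (x−ψⱼ)₊, −I(x>ψⱼ)] and update
each ψⱼ by the ratio of its jump coefficient γⱼ to its slope-change
coefficient βⱼ. Updates are damped by step halving until the profile RSS
does not increase and the breakpoints stay separated; without damping the
bare update routinely collapses breakpoints on realistic data.

Two convergence notions are distinguished deliberately:

- **Estimation at a known k** (`fit_piecewise`, the bootstrap): any local
  minimum of the profile RSS is accepted, including *kink minima* — optima
  at non-differentiable points of the RSS surface, where the linearized
  iteration has no fixpoint and oscillates within one observation gap.
  These are genuine least-squares solutions; rejecting them would simply
  lose the optimum whenever it falls at or near an observed x. Starting
  values are equally spaced breakpoints with deterministic jitter, plus a
  greedy forward-selection start, with a coordinate-descent rescue when
  the iteration stalls far from a solution. On simulated identifiable
  data (n ≤ 60, up to two well-separated breakpoints) this matches an
  exhaustive grid search over observed-x breakpoint placements to within
  1 % RSS.
- **Model ranking** (`rank_models`): a candidate model enters the AICc
  comparison only if the linearized iteration reaches a true fixpoint
  (max |Δψ| < 10⁻⁶ h, jump coefficients at zero) with every breakpoint
  showing a non-zero slope change and every segment holding ≥ 3 hourly
  observations. AICc and the slope t-tests presuppose a regular interior
  optimum — a vanishing score and a valid local quadratic approximation —
  which a kink minimum does not provide. The practical consequence is
  intentional: on featureless data the spurious "best" breakpoints are
  almost always kink minima chasing noise, and excluding them keeps the
  selection honest (k = 0 is selected on white noise in ≥ 90 % of runs).
  Ranking uses restrained starts (equally spaced ± jitter, plus the
  previous model's breakpoints with one more placed at its worst-fitted
  observation — the step-by-step introduction of complexity); an
  exhaustive search would again manufacture support for spurious
  breakpoints. After selection, the chosen k is re-fitted with the
  unrestricted estimation search (two-stage select-then-refit).

AICc = n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1) with p = 3 + 2k (intercept,
k+1 slopes via k slope changes, k breakpoint locations, residual
variance). Models within 2 AICc units of the minimum are treated as
equally supported and the one with fewer breakpoints wins — the standard
information-theoretic reading, and the right asymmetry here because a
false breakpoint asserts a behavioural response that never happened.

A breakpoint is *validated* when the segment slope before or after it
differs from zero by a two-sided t-test (α = 0.05, n − (k+2) df).
Breakpoint uncertainty comes from a case-resampling bootstrap: resample
the hourly (x, y) pairs with replacement, refit at fixed k starting from
the original breakpoints, and take 2.5/97.5 percentiles per rank-ordered
breakpoint across converged replicates (B = 50, a standard choice for
broken-line bootstraps; a residual-resampling variant is available).
Replicates that fail to converge are excluded and logged; if fewer than
60 % converge the CI is flagged unreliable. Percentile CIs at B = 50 are
mildly anti-conservative; simulated coverage of the 95 % interval at
moderate signal-to-noise is ~89 %.

## Response classification

With release at hour 0 and exposure at hour E: the capture-recovery
duration is the earliest validated breakpoint. A noise response is
declared iff some validated breakpoint ψⱼ lies within ±2 h of E or its CI
covers E, *and* the post-ψⱼ slope is significant; the response duration is
ψⱼ₊₁ − ψⱼ and the recovery duration ψⱼ₊₂ − ψⱼ₊₁ (in strict mode those
later breakpoints must themselves be validated; a lenient mode reports
them regardless). Validated breakpoints attributable to neither
disturbance are reported as unrelated behavioural changes. Absence of any
response is a valid outcome, not an error.

One structural limitation: when the underlying response is an
instantaneous level shift, a continuous broken line fitted to hourly means
must spread the shift over a segment holding at least three hourly
observations, so the onset breakpoint is biased early by ~1–3 h (more when
diel-baseline contamination adds a slow pre-onset drift). Gradual-onset
responses do not suffer this. The ±2 h coincidence tolerance is a
parameter for exactly this reason.

## Acoustic exposure

Received levels at range r (metres) are source − 17·log₁₀(r) for each of
L_pp (216 dB re 1 µPa pp at 1 m), L_eq-fast (195 dB re 1 µPa RMS over
125 ms — approximately the porpoise auditory integration time) and SEL
(186 dB re 1 µPa²s), an empirical shallow-water transmission-loss model
valid for r ≥ 1 m. The animal's range at exposure is the great-circle
distance from the GPS fix nearest in time to the exposure start (ties go
to the earlier fix; a fix more than 6 h away raises a warning), and
carries a ±50 % error band: maximum level at 0.5r, minimum at 1.5r.
Reported values are rounded to the nearest integer dB, halves away from
zero. The three metrics differ by constant source offsets (L_pp − SEL =
30 dB, L_eq-fast − SEL = 9 dB) at every range. Audiogram (frequency)
weighting requires band-level spectra that a broadband level cannot
provide; the `weighting_offset_db` hook accepts an externally derived
scalar correction, and no weighted levels are claimed.

## Synthetic data

The generator emulates a tagged odontocete: each parameter follows
baseline + diel cosine + stationary AR(1) noise (per event) + injected
response. The injected response is piecewise linear — a capture offset at
release decaying to zero over the capture-recovery time (default 18 h),
and an optional noise offset held constant over a plateau (default 6 h)
after the exposure (default 96 h into a 240 h deployment) with a linear
ramp back over the recovery (default 24 h). Default magnitudes follow the
responses reported for wild harbour porpoises: speed +5 m/s at release
over a ~1 m/s baseline (a > 500 % increase), more directed movement
(turning-angle offset −30°), dives ~5 s shorter, ~2 m shallower, ~5 m less
wiggly with ~10 s shorter surface pauses; the noise response re-uses the
same directions with speed +2 m/s, no wiggliness change, and −15 s
post-dive pauses. Surfacings occur at exponential intervals (mean 40 s);
each yields a GPS fix with probability 0.25; depth is continuous at 1 Hz
with trapezoidal dives (1.5 m/s descent/ascent) and a sinusoidal bottom
wiggle sized to hit the target wiggliness within the deepest 20 % of the
dive. A single global seed drives everything through per-stream
sub-generators, so outputs are byte-identical across runs.

What the generator does *not* emulate: bursty (non-stationary) speed,
tidal currents and drift, depth-dependent dive shapes, prey patches,
GPS position error (fixes are exact, so the outlier screen sees only
behaviour, never noise spikes), or tag failure. Passing recovery tests on
this data shows the statistical machinery recovers known structure under
the stated noise model — not that real porpoise data are this well
behaved.

Ground truth records, per parameter, the times at which the injected
offset profile changes slope and the corresponding segment slopes. The
abrupt shift at the exposure is a genuine discontinuity recorded as a
breakpoint; as noted above, its recovered location is structurally biased
a few hours early.

## Problem sizes used in validation

The test suite exercises: 240-hour hourly series for breakpoint
selection (50 seeds each for specificity on white noise and sensitivity
at 1/40-amplitude noise); 100 random series of n ≤ 60 with 0–2
well-separated breakpoints for the grid-oracle comparison; 200
moderate-signal hinge series (n = 150) for bootstrap CI coverage; and
full simulate→analyse→compare runs on 10-day deployments. These sizes
match the scale of real deployments (6–12 days, ~1 fix per 2–3 min,
1 Hz depth).

## Known limitations

- Breakpoint onset bias for instantaneous shifts (see above).
- φ from FGLS is inflated when sustained responses are present; it is a
  nuisance parameter here, not an estimand.
- AICc-based selection among broken-line models has no exact
  distributional justification (the breakpoint count is a non-regular
  parameter); the regular-fixpoint admission rule and the 2-unit
  parsimony band are pragmatic calibrations, validated by simulation, not
  theory.
- The turning-angle series is bounded (0–180°) and modelled on the
  identity scale; its residuals are heteroscedastic near the bounds.
- The transmission-loss model is a single empirical log-range fit for
  shallow water; no bathymetry- or sediment-dependent propagation.
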