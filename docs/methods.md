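# Methods

`vgrf` predicts four per-step characteristics of the vertical ground
reaction force (vGRF) during treadmill running — active peak (BW), impact
peak (BW), stance impulse (BW·s), and contact time (s) — from 3-D sacral
acceleration, and evaluates the predictors against two literature baselines
and a mean regressor. Because the kind of paired force-plate/IMU dataset
this pipeline consumes is rarely shareable, the package ships a synthetic
cohort generator with exact per-step ground truth; every stage is validated
against that generator's closed forms.

## The stance waveform model

Each simulated stance is

    F(t) = m·g·[ A·sin(πt/T_c) + I·exp(−(t − f·T_c)² / (2w²)) ],  t ∈ [0, T_c]

and zero during flight. The half-sine carries the active peak `A` at
mid-stance; the optional Gaussian bump adds an impact transient at fraction
`f ≤ 0.10` of stance with width `w`. This is the simplest waveform with the
canonical rearfoot-strike morphology (impact peak in the first 10 % of
stance, larger active peak near mid-stance) that still admits closed forms:
the normalized impulse is `2·A·T_c/π` plus a truncated-Gaussian bump term,
and threshold-crossing times are root-findable analytically. Those closed
forms are the oracles for the extraction tests.

Vertical sacral acceleration follows from whole-body dynamics,
`a(t) = F(t)/(m·g) − 1` in gravity-subtracted g units (flight = −1 g,
standing = 0 g). AP/ML channels are i.i.d. Gaussian sensor noise; no drift
model. Neck-base and L5-base channels (for the trunk-segment baseline)
carry the whole-body vertical signal plus independent noise. Whether a real
device's vertical channel is gravity-compensated varies by vendor, so the
convention is a cohort flag (`gravity_subtracted`, default true); the
pipeline shifts raw channels by −1 g before thresholding when it is false.

### Generator population, defaults and why

Per-step stance parameters have linear speed trends with subject-level
random intercepts, so speed is informative and subjects are exchangeable
only at the subject level (making subject-wise splitting meaningful):

| parameter | mean @ 2.71 m/s | speed slope | subject SD | step SD |
|---|---|---|---|---|
| active peak A (BW) | 2.44 | +0.25 /(m/s) | 0.15 | 0.08 |
| contact time T_c (s) | 0.26 | −0.045 /(m/s) | 0.018 | 0.008 |
| step period (s) | 0.36 | −0.03 /(m/s) | 0.012 | 0.006 |

Defaults: four protocol speeds (2.22, 2.50, 2.78, 3.33 m/s), force at
1200 Hz, acceleration at 240 Hz, accelerometer noise SD 0.08 g per channel,
force-plate noise SD 5 N, impact-bump probability 0.41, body mass
74 ± 11.9 kg. Bump parameters are drawn so the total curve value at the
bump apex is ~1.65 ± 0.15 BW, with the amplitude floored at the level that
makes the bump an unambiguous local maximum over the rising half-sine
(slope-dominance condition) — simulated impact peaks are detectable by
construction, which is what lets the detection-iff-present property be
tested exactly.

A consequence of the half-sine shape is that the impulse is *determined*
by A and T_c (≈ 2AT_c/π ≈ 0.40 BW·s at the default means); real force
curves have a lower shape factor (~0.58 rather than 2/π ≈ 0.64), so one
cannot simultaneously match typical human means of all three of
{active peak, impulse, contact time} with this waveform. The generator
targets the active-peak and contact-time means and lets the impulse follow
its closed form; the distributional test checks exactly that.

## Preprocessing

Force is low-passed with a 5th-order Butterworth at 30 Hz, acceleration at
60 Hz, both applied forward–backward (zero phase) so event timing is
preserved; the effective gain is |H(f)|², i.e. 0.5 at the cutoff.
Odd-reflection padding of 3× the filter order avoids edge transients.
Forces are normalized to body weight with g = 9.81 m/s² exactly. Mixed
sampling rates are handled by linear interpolation onto the target grid
(exact for ramps, adequate for the ≤ 60 Hz content that survives
filtering). Trials are assumed time-aligned at t = 0; the stored trial CSV
keeps each channel block on its own time column so native rates round-trip
exactly.

## Event detection

Force-plate stances are contiguous regions with F > 50 N (applied to the
filtered, un-normalized signal, since 50 N is absolute); regions touching
the trial boundary are incomplete and dropped.

Acceleration initial contact starts from upward crossings of +0.18 g,
constrained by (i) a rise to ≥ +0.5 g within 0.10 s after the crossing,
(ii) a value ≤ 0 g within 0.10 s before it, and (iii) a 0.2 s refractory
period. On a smooth stance curve the +0.18 g crossing necessarily lags the
true touchdown by tens of milliseconds, so the retained candidate is
refined backwards to the last upward crossing of a contact-onset level
(default −0.95 g, just above the −1 g free-fall floor) inside the lookback
window; this pins the IC to within ~2 samples (240 Hz) of the true stance
onset on noiseless data. Toe-off is the last downward crossing of −0.25 g
before the next IC, relaxed in +0.05 g steps to at most −0.05 g when
absent, then refined forward to the next downward crossing of the onset
level. All thresholds are config-exposed (`EventConfig`).

Acceleration- and force-detected steps are matched greedily one-to-one by
nearest IC time with a 0.05 s tolerance; unmatched steps are dropped.
Steps survive filtering when the force-plate stance duration lies in
[0.167, 0.4] s (inclusive), the window has no NaN, and the stance peak
reaches ≥ 1.2 BW (operationalization of "signal falling away" corruption).

## Characteristics

Active peak = global stance maximum (safe because impact transients are
smaller by definition). Impact peak = first local maximum (prominence
≥ 0.05 BW) within the first 10 % of stance samples; absent otherwise. The
active peak deliberately does not exclude the first-10 % window. Impulse =
trapezoidal integral (adequate at 1200 Hz for 30 Hz-band-limited signals).
Contact time = stance duration. The window fraction and prominence floor
are config-exposed.

## Features

Three provenance families per step: **subject** (mass, leg length),
**domain** (step frequency, vertical-acceleration impulse over stance and
over the entire step), and **general** — a frozen, versioned catalogue
(`v1`) of 16 descriptors computed independently per axis (vertical, AP,
ML): mean, SD, min, max, median, skewness, excess kurtosis, RMS, absolute
energy, mean-crossings, autocorrelation at lags {1, 5, 10}, dominant DFT
frequency (Hz) and magnitude, and linear-trend slope, plus the window
duration. Features are computed on the native sampling grid (spectral
features are reported in Hz, hence window-length invariant); no cross-axis
features. Windows are the stance (IC–TO) for the active-peak, impact-peak
and contact-time models and the entire step (IC–next IC) for the impulse
model, a per-target default that can be switched in `FeatureConfig`.

Cleaning drops any feature with a missing value or zero variance and
one-hot encodes categoricals. Standardization is a per-column z-score
(population SD) fitted on training rows only — re-fitted inside every
cross-validation fold — with one-hot indicators exempt.

## Models and evaluation

The predictor is the Lasso, minimizing `(1/2n)·RSS + λ‖β‖₁` with an
unpenalized intercept (scikit-learn's coordinate descent, tolerance 1e-7),
fitted on standardized features. λ is selected over a 20-point log-spaced
grid in [5e-6, 0.05] by leave-one-subject-out cross-validation on the
training subjects; the validation score is the unweighted mean of per-fold
RMSE and ties break toward the larger λ. Inside the CV loop, a single
warm-started coordinate-descent path per fold (strong λ first) produces
numerically identical fits to independent per-λ fits, at a fraction of the
cost. Speed enters, when enabled, as one numeric feature. Steps without a
detected impact peak are excluded from the impact-peak task (training and
evaluation); this is not configurable.

Subjects are split into disjoint train/test sets (default fraction 7/43,
reproducing a 36/7 split of 43 subjects). Metrics: RMSE, MAPE in percent,
and R² computed against the evaluation split's own mean (so a baseline can
score negative R² on test). Per-speed evaluation partitions the test set
by trial speed; step-weighted per-speed MSEs sum exactly to the overall
MSE.

Baselines share the identical split and step sets: (1) a mean regressor;
(2) an Alcantara-style model per target (active peak, impulse, contact
time): the vGRF is estimated as m·g·(a+1), clipped at zero, the matched
characteristic is read off it over the acceleration-detected stance, and
OLS maps {estimate, mass, speed} to the target; (3) a Veras-style
single-segment model for the impact peak: trunk CoM acceleration is the
linear interpolation between neck-base and L5-base channels
(CoM fraction 0.4486), the segment curve
`trunk_mass_fraction·m·g·(a_com+1)` (mass fraction 0.4346, both
config-exposed) is expressed in whole-body BW for unit consistency, and
its impact peak — extracted with the same operator as the force-plate one —
is calibrated to the true impact peak by OLS. Steps whose segment curve
shows no impact peak are excluded and logged.

## Numerical choices and problem sizes

* Reference end-to-end runs use 20 subjects × 4 speeds × 15 s trials
  (~3,800 steps); distributional checks use 40 subjects; event-recovery
  checks use noiseless 4-subject cohorts. These sizes give stable estimates
  at desk scale.
* All randomness flows from one integer seed through named
  `SeedSequence` sub-streams (simulate, split), with per-subject child
  streams so enlarging a cohort never perturbs existing subjects. Repeat
  runs are bitwise identical.
* The distributional-sanity test uses a cluster-robust SE (SD of subject
  means / √n_subjects), since steps within a subject are correlated and a
  naive per-step SE would be anticonservative.
* Degenerate inputs: empty stance windows, non-positive masses, cutoffs at
  or above Nyquist, unmatched toe-offs and zero-variance training columns
  all raise or are dropped with logged warnings rather than propagating
  NaN.

## Known limitations

* The generator's acceleration is exactly (scaled) force plus noise;
  real sacral acceleration contains soft-tissue artefact, posture-dependent
  gravity components and axis cross-talk. Passing recovery tests therefore
  demonstrates correctness of the pipeline's logic, not field accuracy on
  human data.
* The general-feature catalogue is a compact stand-in for the much larger
  automatic catalogues used in practice; `general_ts_features` is the
  single extension point for plugging in a fuller list.
* Left/right foot attribution, overground running, gyroscope channels and
  loading-rate outcomes are out of scope.
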