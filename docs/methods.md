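# Methods

`finpulse` reimplements, as a tested and reusable pipeline, an analysis
workflow for quantifying the association between seismic airgun shooting
and fin-whale 20-Hz pulse detections in passive acoustic monitoring (PAM)
records from ocean-bottom seismometers and hydrophones.  The pipeline has
five stages — synthetic annotated scenes, a PCEN spectrogram frontend, a
CNN frame detector with evaluation tooling, hourly/period aggregation
feeding a negative-binomial mixed model, and a worst-case masking
correction with trend reporting.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Synthetic acoustic scenes

Real survey audio is large and access-controlled; every stage is
therefore exercised against a generator that emulates the statistical
structure the analysis relies on:

- **Fin-whale 20-Hz pulse**: a 1.0-s linear downsweep from 23 to 18 Hz
  with a Hann amplitude taper, unit RMS, mixed at a configurable SNR
  (dB, relative to broadband ambient power).  The parameter choice is the
  classic description of the call — a ~1 s downsweep centred near 20 Hz —
  and every number is configurable.
- **Airgun shots**: exponentially decaying broadband transients, low-pass
  shaped below 100 Hz, fired on a fixed cycle (default every 16 s, the
  firing interval of a dual-array seismic survey).  Each shot's *masking
  duration* — the stretch of spectrogram it obscures — is drawn uniformly
  within (2.7, 7.7) s and recentred so the draw mean is 5.5 s (clipped
  back into the range), matching measured masking footprints.  Only the
  timing/bandwidth/masking statistics matter downstream, so no
  propagation physics (spreading, multipath, instrument response) is
  modelled.
- **Ambient noise**: 1/f ("pink") Gaussian noise by default, slope
  configurable; typical deep-ocean low-frequency ambient is between pink
  and red.
- **Pulse scheduling**: homogeneous Poisson process (default 2
  pulses/min).  Fin-whale song has regular inter-call intervals; a
  Poisson schedule is deliberately simpler, because no downstream stage
  uses call timing beyond frame occupancy, and PAM analyses of this kind
  found no diel structure worth emulating.

Scenes are reproducible bit-for-bit under a seed, and every event is
returned in a ground-truth list from which 30-s frame labels are derived
(a frame is positive iff a whale pulse overlaps it; airgun shots never
set the label).

Labelled 30-s frames for detector work come from the same generator.
Positive frames carry exactly one pulse; when airgun shots are included
(half of the frames of both classes, so the detector must both reject
shots and find calls between them), the pulse onset is drawn from the
gaps between the shots' masked intervals — a call fully under a shot is
undetectable in principle, so labelling it positive would poison the
ground truth.  That in-principle loss is precisely what the downstream
masking correction accounts for.

**What passing tests on synthetic scenes do not show**: real-data
detector metrics.  Synthetic pulses are stereotyped and the noise space
is far narrower than a real soundscape (no shipping, no flow noise, no
other species, no instrument artefacts).  Detector results here
demonstrate that the pipeline trains and discriminates as designed, not
that any particular accuracy transfers to field recordings.

## Hourly count simulator

Hourly counts of pulse-positive frames are simulated directly from the
inference model (below): log-scale period fixed effects, Gaussian random
intercepts per instrument (SD 0.12) and per instrument-day (SD 0.43),
NB2 observation noise (θ = 6.22).  The default fixed effects are the
log marginal means of the four survey periods (64.6 / 57.1 / 18.5 / 15.4
frames per hour for Quiet 1 / Quiet 2 / Shooting 1 / Shooting 2); the
default layout is 3 instruments × 63 days (day-of-year 156–218) × 24 h.
These defaults make the simulator a parameter-recovery harness for the
fitter at realistic effect sizes and sample sizes.

## Spectrogram frontend

30-s segments at 200 Hz (250-Hz instruments are decimated with a
polyphase anti-alias filter; upsampling is refused) are transformed with
a Hann-windowed 256-point FFT at 75% overlap — windows slide from sample
0 with no boundary padding, giving floor((6000−256)/64)+1 = 90 time
frames — then band-limited to 4–80 Hz (97 bins of 0.78125 Hz).

Per-channel energy normalisation (PCEN) is applied per frequency
channel:

    M[t] = (1 − s)·M[t−1] + s·E[t],   M[0] = E[0]
    out  = (E/(ε + M)^α + δ)^r − δ^r

with defaults α = 0.98, δ = 2, r = 0.5, s = 0.025, ε = 1e−6 — the widely
used audio-event-detection operating point.  PCEN suppresses stationary
and slowly varying background (and compresses loud transients) while
emphasising onsets, which is what makes 20-Hz pulses stand out between
airgun shots.

The normalised (90 × 97) array is bilinearly resized to 97 × 90
(time × frequency), min–max scaled to [0, 1] (a constant array maps to
zeros), and replicated into three identical channels, producing the
97 × 90 × 3 tensor an image-classification backbone expects.  The
declared tensor shape does not follow from the STFT arithmetic (which
gives 90 × 97), so the resize is the explicit, pinned bridge between
the two; axis order and ascending frequency are fixed for reproducible
tensors.

## Detector

A binary classifier over the 97 × 90 × 3 tensors: a convolutional
feature extractor, global average pooling, then a classification head of
two dense layers (512 and 256 rectified-linear units) with dropout 0.5
and 0.2, and a 2-unit softmax.  Dense weights are Glorot-uniform with
zero biases.  Training minimises categorical cross-entropy with Adam and
a staircase-decayed learning rate: 0.001 × 0.75^floor(step/90).  Each
frame is classified independently of its chronological context by
construction, and a probability ≥ 0.5 is a detection (ties count
positive; 0.5 is the rounded ROC-optimal threshold for this detector
family).

The default `small_conv` backbone is two 3×3 convolution blocks (8 and
16 channels, ReLU, 3×3 max pooling) — a few thousand weights that train
in minutes on one CPU in single precision.  The backbone is the one
deliberately scaled-down component of the pipeline: large pretrained
image backbones are out of scope because the object under test is the
analysis, not transfer learning, and the package must be reproducible at
desk scale.  An `efficientnet_b0` backbone name is reserved and raises,
so configurations written for a heavyweight runtime fail loudly rather
than silently degrade.

Detectability under shooting is physically limited in the synthetic
scenes, as in the field: PCEN's smoother (time constant ≈ 13 s at
s = 0.025) recovers slowly after a 20-dB shot, so pulses in the gaps
between shots are partially suppressed, and frame-level discriminability
on airgun-contaminated scenes sits well below the clean-scene level
(tested as AUC ≥ 0.80 vs ≥ 0.95 clean).  This is the acoustic-masking
phenomenon the correction stage quantifies, not a detector defect — a
band-energy oracle shows the same gap.  The detector sanity benchmark is
therefore defined on clean high-SNR scenes, with the airgun-mixed
condition kept as a separate robustness check.

Evaluation (confusion counts, precision/recall/F1, FPR/FNR, ROC with
trapezoid AUC) follows the standard definitions; ratios with zero
denominators are reported as missing with a warning, never as silent
zeros.  The "optimal" ROC threshold maximises Youden's J = TPR − FPR,
ties broken toward 0.5.

## Aggregation

Detections are counted per instrument-hour (at most 120 non-overlapping
30-s frames per hour).  Hours with no usable frames are flagged invalid
and excluded everywhere — never imputed as zero.  Day-of-year ranges
partition the record into Shooting 1 (156–173), Quiet 1 (174–196),
Shooting 2 (197–212), Quiet 2 (213–218); any day with any shooting is a
shooting day.  Pooled quiet/shooting means per instrument are
hour-weighted by default (the rule consistent with published pooled
values, e.g. (74.4×23 d + 83.0×6 d)/29 d = 76.2); simple averaging of
the two period means is available as an option.

## Period-contrast mixed model

The inference engine is an NB2 generalised linear mixed model:

    count ~ NB2(μ, θ),  Var = μ + μ²/θ
    log μ = Xβ + b_inst + b_inst:day,
    b_inst ~ N(0, σ²_inst),  b_inst:day ~ N(0, σ²_day)

with Period the fixed effect.  Cell-means coding is the default (each
coefficient is directly the log expected hourly count of a period with
random effects at zero); treatment coding with a configurable reference
is available.

**Estimation.**  The marginal likelihood is maximised under a Laplace
approximation over the random effects.  For a candidate parameter
vector, the joint random-effect mode is found by damped Newton
iteration; because days are nested in instruments the penalised Hessian
is arrowhead-sparse per instrument (a diagonal over its days plus one
coupling row), so each Newton solve and the log-determinant come from a
linear-time Schur factorisation.  The outer optimisation over
(β, log σ_inst, log σ_day, log θ) uses L-BFGS-B with finite-difference
gradients whose step (1e−5) is set well above the inner solver's noise
floor, runs a second pass from the incumbent with a reset random-effect
state (guarding against stalls on the flat ridge between β and the mean
instrument intercept), and falls back to a derivative-free Nelder–Mead
polish if line searches fail.  Convergence tolerance is 1e−6 relative;
mu-independent likelihood terms are evaluated once per candidate via the
unique observed counts.  On identical data the fitted coefficients,
standard errors, variance components, dispersion and log-likelihood
match the standard R mixed-model fitter for this family (glmmTMB) to
three to four significant figures.

**Inference.**  Wald: the covariance of all parameters is the inverse of
a central-finite-difference Hessian of the negative Laplace
log-likelihood at the optimum (spectrum clipped to positive if the
numerical Hessian is indefinite, with a warning).  Estimated marginal
means are the exponentiated per-period linear predictors with random
effects at zero; CIs are exponentiated Wald intervals on the log scale.
All pairwise period contrasts are reported as rate ratios with a Tukey
multiplicity adjustment computed from the joint normal distribution of
the contrast z statistics — P(max_j |Z_j| ≥ |z_k|) under Z ~ MVN(0, R) —
by Monte Carlo with a pinned seed (the exact studentized-range
distribution does not apply to GLMM contrasts; the max-|z| multivariate
formulation is the standard generalisation).  Adjusted p-values are
floored at the unadjusted ones, so Monte-Carlo noise can never make
adjustment appear anti-conservative.

**Known inferential limitation.**  With only three instruments the
instrument variance component is estimated on ~2 degrees of freedom, so
Wald-z intervals for period means under-cover slightly in simulation
(~89–92% instead of the nominal 95% at the default study layout; the
reference R fitter shows the same behaviour on identical data).
Contrasts between periods are unaffected, because the instrument
intercepts cancel within instrument.

**Diagnostics.**  Simulation-based randomised-quantile residuals:
replicate datasets are simulated unconditionally from the fitted model
(random effects re-drawn), each observation is reduced to its randomised
quantile among its replicates, and uniformity (Kolmogorov–Smirnov), a
dispersion ratio (observed vs simulated response variance, simulation
p-value), and observed-vs-expected zero counts are reported, all under a
pinned seed.

## Worst-case masking correction

Airgun shots obscure part of each shooting period, so some calls are
undetectable in principle.  The correction assumes *every* masked
interval hid a call: masked time per period is shots × mean masking
duration (5.5 s); the masked fraction is masked time over period time;
and observed shooting means are inflated by 1/(1 − mean masked
fraction), where the mean masked fraction is the unweighted mean of the
period fractions (an hour-weighted variant is available).  With the
default shot logs (66,898 shots / 432 h and 84,417 shots / 384 h) this
gives 102 h and 129 h masked, fractions 23.7% and 33.6%, and a factor of
1.40 at two decimals.

Printed-table conventions are pinned and tested: one-decimal half-up
rounding; the two-decimal factor (1.40, not 1.4025) applied when
regenerating the published table; and the worst-case percentage drop
computed from the *rounded* corrected mean — the only convention under
which all per-instrument printed cells reproduce exactly.  Two published
values are documented as non-reproducible from the printed inputs rather
than imitated: the Shooting-1 masked fraction (exact arithmetic gives
23.66%, not 23.5%) and the table's mean worst-case drop of 52.0% (the
mean of the per-instrument worst-case drops is 58.6%).

## Reporting

Daily totals are smoothed with LOESS: locally weighted linear
regression, tricube weights over the span-nearest neighbours (default
span 0.3), no robustness iterations, evaluated at observed days; missing
(corrupt) days are excluded from fitting.  The detection-uncertainty
ribbon scales the smoothed line multiplicatively by the detector error
rates — lower = smoothed × (1 − FPR), upper = smoothed × (1 + FNR),
clipped at zero — reflecting that false positives could have inflated
and false negatives deflated the observed counts.  The additive-vs-
multiplicative form and the direction of each rate are a documented
interpretation choice: multiplicative scaling of the smoothed counts is
the only reading consistent with rate-valued inputs, and the band always
contains the line.  Box summaries use linear-interpolation (type-7)
quantiles with whiskers at the most extreme points within 1.5 × IQR.

## Problem sizes used in the test suite

The acceptance-level checks run at deliberately chosen desk scales: the
parameter-recovery study uses 200 replicates of the default 3 × 63 × 24
layout (~4,500 observations each); the detector sanity check trains on
2,000 synthetic frames at 10 dB SNR and evaluates on a held-out set;
table arithmetic and worked examples are exact and instantaneous.  These
sizes are the package's reference conditions and are fixed in the tests.
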