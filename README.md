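# finpulse

Passive acoustic monitoring (PAM) from ocean-bottom seismometers and
hydrophones can record fin whales (*Balaenoptera physalus*) and the
seismic airgun surveys that disturb them at the same time.  `finpulse`
is a tested, desk-reproducible pipeline for the analysis that question
requires: detect fin-whale 20-Hz pulses in 30-second spectrogram frames
with a CNN, aggregate detections into hourly counts across survey
periods, contrast quiet against shooting periods with a
negative-binomial mixed model, and bound how much of the observed drop
in calling could be an artefact of airgun shots acoustically *masking*
the calls.

It is written for bioacousticians and quantitative ecologists who want
the full chain — from waveform to corrected effect size — as a library
of scikit-learn-style estimators with a thin CLI, runnable end to end on
one CPU with synthetic data, so every stage is testable without access
to the original recordings.

## The models

**Detection.**  30-s segments at 200 Hz are transformed to Hann-windowed
magnitude spectrograms (256-point FFT, 75% overlap), band-limited to
4–80 Hz, normalised with per-channel energy normalisation

    M[t] = (1 − s)·M[t−1] + s·E[t],    out = (E/(ε + M)^α + δ)^r − δ^r

and resized to a 97 × 90 × 3 tensor.  A small convolutional network
(global average pooling, dense 512 → 256 head with dropout 0.5/0.2,
2-unit softmax) is trained with Adam under a staircase-decayed learning
rate (0.001 × 0.75^⌊step/90⌋).  A frame with pulse probability ≥ 0.5 is
a detection; detectors are evaluated with precision/recall/F1 and ROC
AUC, with the operating threshold chosen by Youden's J.

**Inference.**  Hourly counts y of pulse-positive frames follow an NB2
mixed model with log link:

    y ~ NB2(μ, θ),   Var(y) = μ + μ²/θ
    log μ = β_period + b_instrument + b_instrument:day

fitted by maximum likelihood with a Laplace approximation over the
nested random intercepts.  Per-period estimated marginal means
exp(β_period) are reported with Wald CIs, and all pairwise period
contrasts as rate ratios with Tukey-adjusted p-values.

**Masking bound.**  Each airgun shot obscures ~5.5 s of spectrogram.
With shots every ~16 s, the masked fraction f of each shooting period is
computed from the shot log, and observed shooting-period means are
inflated by the worst-case factor 1/(1 − f̄) — assuming every masked
interval hid a call.  A drop that survives this correction cannot be a
masking artefact.

## Worked example

Regenerate the masking-correction table from a survey's printed inputs
(pooled quiet/shooting means per instrument; shot logs of 66,898 and
84,417 shots over 432 h and 384 h; mean mask 5.5 s):

```python
>>> import finpulse as fp
>>> res = fp.build_table1({"OBS18": (76.2, 16.6),
...                        "OBS46": (58.4, 16.2),
...                        "OBH56": (67.8, 26.6)})
>>> res.masked_hours_rounded
{'Shooting 1': 102, 'Shooting 2': 129}
>>> res.correction_factor_rounded
1.4
>>> print(res.table.to_string())
  instrument  quiet_mean  shooting_mean  pct_drop_observed  corrected_shooting_mean  pct_drop_worst_case
0      OBS18        76.2           16.6               78.2                     23.2                 69.6
1      OBS46        58.4           16.2               72.3                     22.7                 61.1
2      OBH56        67.8           26.6               60.8                     37.2                 45.1
>>> res.mean_pct_drop_observed
70.4
```

Reading the table: detections dropped 60.8–78.2% during shooting
(mean 70.4%).  Of each shooting period, 102 h / 432 h and 129 h / 384 h
were masked (23.7% and 33.6%, mean 28.6%), giving a worst-case
correction factor of 1.40.  Even if *every* masked interval hid a call,
the corrected shooting means (e.g. 16.6 × 1.40 = 23.2 frames/h) still
sit 45.1–69.6% below the quiet means — the decline in calling is real,
not a detection artefact.

And the statistical engine on simulated survey-scale data:

```python
>>> counts = fp.simulate_counts(fp.CountSimConfig(seed=0))   # 3 instruments x 63 days x 24 h
>>> fit = fp.fit_nb_glmm(counts)
>>> round(fit.theta_, 2), round(fit.sigma_day_, 2)
(6.4, 0.42)
>>> fit.emmeans().round(1)[["period", "emm", "lower", "upper"]]
       period   emm  lower  upper
0  Shooting 1  16.5   13.7   20.0
1     Quiet 1  52.4   43.8   62.7
2  Shooting 2  14.5   12.0   17.6
3     Quiet 2  51.4   40.1   65.9
```

The simulator drew these counts with quiet-period means near 60 and
shooting-period means near 17 frames/h; the fitted marginal means and
dispersion recover those settings within sampling error.

## Command line

```bash
finpulse simulate --config scene.yaml --out scene_dir/   # WAV + ground-truth CSV
finpulse train    --frames frames.npz --out detector.npz
finpulse detect   --frames frames.npz --model detector.npz --out detections.csv
finpulse evaluate --labels labels.csv --probs detections.csv --out metrics.json
finpulse model    --counts counts.csv --out fit.json
finpulse report   --counts counts.csv --out-dir report/   # LOESS trend + boxes
```

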