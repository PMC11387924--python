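# nightvitals

Evaluation of contactless nocturnal vital-sign monitors against
polysomnography (PSG), together with a synthetic overnight-cohort
generator so the whole pipeline runs with no external data.

## The problem

Undermattress and bedside "nearable" sensors report per-epoch heart rate
(bpm), breathing rate (cpm), and breathing-disturbance summaries (snore
flags, apnea-hypopnea index) overnight. Validating them against PSG is an
exercise in method-agreement statistics over harmonized epoch series:
device and reference run on different grids (30-s vs 60-s epochs, 4-s
substeps), their clocks disagree by up to minutes, devices quantize,
clip, and drop estimates, and the comparison must respect the sleep
staging context. `nightvitals` implements that evaluation as a reusable
library for sleep researchers and device-validation teams.

## What it computes

For valid device/reference epoch pairs (d_i, r_i), with difference
series x_i = d_i − r_i:

- **Bland-Altman**: bias = x̄, limits of agreement LoA = bias ± 1.96·s_x,
  with parametric 95% CIs (SE_bias = s/√n, SE_LoA = s·√(3/n));
- **MDC** (minimum detectable change) = (LoA_upper − LoA_lower)/2 ≡ 1.96·s_x;
- **MAE** = mean|x|, **MAPE** = mean(|x|/r)·100, pooled over pairs or
  aggregated per participant;
- **SAD**: the directionless Cohen's *d* of the discrepancy,
  |d̄ − r̄| / pooled SD;
- **ICC(2,1)**: single-measure absolute-agreement intraclass correlation
  from two-way random-effects ANOVA mean squares, CI by the F-method;
- **r²** from simple linear regression, **MCC** for 2×2 confusions, and
  empirical absolute-error quantiles/CDFs.

Upstream of the statistics: reference heart rate from beat timestamps
(interval means of 60/RR per 30-s epoch), breathing rate from
inspiratory-peak intervals, snore scoring (30 dB threshold, 300 ms
minimum duration), AHI with the standard severity bins (<5 normal,
5–<15 mild, 15–<30 moderate, ≥30 severe), cross-correlation clock
alignment over ±5 minutes, and temporal-resolution analysis at 1/10/60
minute windows.

The synthetic generator emulates the study conditions: a Markov-chain
consensus hypnogram over W/N1/N2/N3/REM/no-presence at 30-s epochs,
stage- and time-dependent vitals (beat timestamps and an FM respiration
waveform), Poisson apnea/hypopnea events, snore episodes with dB
intensities, and three device observation models (60-s integer-rounded
outputs with clipping; 4-s-substep heart rate averaged to 30 s;
breathing-rate-only with wake-concentrated missingness).

## Worked example

```python
import nightvitals as nv

cfg = nv.SimulationConfig(n_participants=8, night_duration_s=14400, seed=1)
cohort = nv.make_cohort(cfg, [nv.wsa_model(), nv.emfit_model()], seed=1)
results = nv.DeviceEvaluation(cohort, "emfit").fit()
print(results.all_night["hr"].summary())
```

prints

```text
Paired agreement (hr, bpm) — emfit all-night
======================================================
n pairs               8
device mean (SD)      59.94 (8.80) bpm
reference mean (SD)   59.58 (8.89) bpm
bias (SD)             0.36 (0.12) [0.26, 0.46]
LoA lower             0.13 [-0.04, 0.30]
LoA upper             0.59 [0.42, 0.76]
MDC                   0.23 bpm
MAE                   0.36 [0.26, 0.46]
MAPE                  0.63% [0.41, 0.86]
SAD                   0.04 [0.03, 0.12]
ICC(2,1)              1.00 [0.77, 1.00]
r^2                   1.00
```

Eight simulated 4-hour nights: the device's nightly-mean heart rate runs
0.36 bpm above the reference (its configured bias plus residual noise), the
smallest change distinguishable from measurement error is 0.23 bpm, MAPE is
well under the 10% acceptability limit, and reliability is excellent
(ICC 1.00). `results.acceptable["hr"]` is `True` accordingly.

The same object carries stage-stratified reports (`results.stages`),
temporal-resolution tables with error quantiles
(`results.multiresolution`), overnight time courses
(`results.time_courses`), and the snore/AHI concordance analyses.

A CLI wraps the pipeline end to end:

```sh
nightvitals simulate --config cohort.yaml --out cohort/ --seed 1
nightvitals harmonize --in cohort/ --max-lag 300 --out aligned/
nightvitals evaluate --cohort cohort/ --devices wsa,emfit --out report/
nightvitals run-all --config cohort.yaml --out run/ --seed 1
```

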