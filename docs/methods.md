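# Methods

This note records the models behind `nightvitals`, the parameter choices
that matter, and what the synthetic cohorts do and do not establish.

## Epoch model and pairing

All comparisons run on uniform epoch grids addressed by left edges of
half-open intervals `[t, t + epoch_s)`; the reference grid is 30 s.
Device series on 60-s grids are upsampled by value duplication (an
explicit choice over interpolation: a device that reports one value per
minute asserts that value for the whole minute); finer series are
downsampled by the mean of present sub-values, missing only when every
sub-value is missing. A pair is valid when both values are present and
neither hypnogram scores the epoch artifact or no-presence. Pairs carry
the reference stage label so stratified analyses need no re-pairing.

## Clock alignment

Device clocks are offset from the PSG by an unknown lag, searched in
30-s steps over ±300 s. The objective is the equal-weight sum of
(a) the Pearson correlation of the mean-centered overlapping vitals and
(b) the hypnogram epoch-agreement fraction after mapping both stagings
to the common 4-state vocabulary (N1, N2 → LS; N3 → DS). Whether the two
criteria should be maximized jointly or sequentially is genuinely open;
the joint sum is symmetric, needs no ordering decision, and recovers
injected lags exactly on clean signals, so it is the default (the
weights are parameters of the internal scorer). Ties break toward the
smallest |lag|, then the negative lag, which pins the degenerate
constant-vitals case to 0. Sub-epoch lags and clock drift are out of
scope: the lag is applied as a pure shift.

## Reference extraction

- **Heart rate**: each beat-to-beat interval contributes an
  instantaneous rate 60/RR to the epoch containing its *ending* beat;
  the epoch value is the mean of contributing rates. The ending-beat rule
  keeps assignment local and causal. Epochs with fewer than two beats
  are missing — a rate requires at least one locally ending interval.
- **Breathing rate**: inspiratory peaks on the detrended band signal with
  a 1.5-s minimum separation and a prominence of at least 0.25× the
  epoch's interquartile amplitude; breath-to-breath intervals are
  converted like RR intervals. A flat signal yields missing values, not
  an error. These are transparent re-implementations of standard toolbox
  chains — functional, not bit-exact, equivalents.
- **Snore**: maximal runs of the intensity trace strictly above 30 dB
  lasting ≥ 300 ms become events; overlapping events are merged before
  durations are summed (how PSG software aggregates overlapping scores
  is unspecified; merging avoids double-counting time).
- **AHI**: respiratory events per hour of sleep, where total sleep time
  is the count of non-wake, non-excluded reference epochs × 30 s.
  Severity bins are half-open with boundaries in the higher class
  (5 → mild, 15 → moderate, 30 → severe).

## Agreement statistics

The LoA multiplier is fixed at 1.96 (configurable); MDC ≡ 1.96·sd of
differences follows identically. CI formulas are the classical
Bland-Altman ones (SE_bias = s/√n, SE_LoA = s·√(3/n), t quantiles).
MAE/MAPE support two aggregations: per-participant (statistics per night
first, then mean and t-interval across nights — the participant is the
unit of replication in all-night tables) and pooled over pairs (used for
resolution analyses where the epoch or window is the unit). The ICC is
fixed to single-measure absolute-agreement ICC(2,1) from two-way ANOVA
mean squares with the McGraw-Wong F-based CI; reliability below 5
subjects is reported NaN rather than estimated. The reported ICC is
clamped to [0, 1] with the raw estimate retained. SAD offers both
candidate denominators — pooled SD of the two samples (textbook Cohen's
d, the default) and SD of the paired differences — because neither can
be singled out as canonical for this statistic; its CI is a seeded
nonparametric bootstrap. The MCC zero-denominator convention is 0.

Acceptability: heart rate passes at MAPE ≤ 10% *or* |bias| ≤ 5 bpm;
breathing rate at |bias| ≤ 4 cpm. Bounds are inclusive (a device meeting
the stated limit exactly is deemed acceptable).

## Synthetic cohort generator

The generator's defaults encode the study conditions rather than tunable
conveniences:

- **Night**: 36 000 s (10-h time in bed), 30-s epochs, first epoch wake.
- **Hypnogram**: first-order Markov chain over W/N1/N2/N3/REM/no-presence.
  The transition probabilities are not published; the defaults were
  calibrated once so the mean simulated total sleep time is ≈386 min of
  the 10-h night with realistic stage occupancies (W ≈ 35%, N1 ≈ 7%,
  N2 ≈ 28%, N3 ≈ 17%, REM ≈ 12%, no-presence < 1%) and are overridable.
- **Vitals**: per-epoch truth = stage mean + overnight trend +
  per-participant offset. Stage means (HR 66/63/61/59/64 bpm,
  BR 15.5/15/14.5/14/15.2 cpm for W/N1/N2/N3/REM) are occupancy-weighted
  to reproduce the cohort laboratory means of ~62.2 bpm and ~14.7 cpm;
  between-participant SDs default to 8.9 bpm and 2.9 cpm. The trend
  falls monotonically from +A/2 to −A/2 at 75% of the night, then rises
  to −A/4 — the characteristic nocturnal decline with a pre-waking
  uptick (A defaults: 3 bpm, 0.5 cpm). Beats are emitted with
  RR = 60/HR(t) plus Gaussian jitter (default SD 0.05 s); respiration is
  a phase-integrated FM sinusoid at the instantaneous breathing rate
  (8 Hz) plus additive noise.
- **Events**: apnea/hypopnea as a Poisson process at `ahi_rate` per
  sleep-hour (default 10 — the cohort's mostly mild-to-moderate apnea),
  each confined to a uniformly chosen sleep epoch; snoring per sleep
  epoch with probability 0.10, intensity Normal(45, 6) dB against a 0-dB
  baseline trace.
- **Devices**: observed = clip(quantize(true + bias + noise)) on the
  device grid, with quantization rounding half away from zero (the
  devices' actual rounding rule is unpublished; this rule is symmetric
  and stated). The presets encode the documented behaviours — `wsa`:
  60-s epochs, quantum 1, HR ∈ [40, 90] bpm, BR ∈ [8, 35] cpm, snore
  flags and a BDI; `emfit`: 30-s epochs with HR estimated at 4-s
  substeps and averaged (per-epoch noise SD shrinks by √m), HR ∈
  [40, 135], BR ∈ [6, 30]; `somnofy`: breathing rate only, BR ∈ [6, 30],
  wake epochs missing with probability 0.6. No quantitative noise model
  is published for any device; the preset bias/noise values are chosen
  at the scale of the published pooled difference SDs and make no
  fidelity claim beyond that. Device hypnograms are the reference
  staging mapped to 4 states with symmetric label confusion (default
  accuracy 0.9; the devices' true staging performance is a separate
  topic, out of scope). Device BDI is generated as exactly twice the
  device AHI, matching the empirical 2:1 relationship the analysis
  exploits (the evaluation uses BDI/2 as the AHI proxy when the device
  reports only BDI).
- **Sub-seeding**: independent streams keyed by (master seed,
  participant, channel, device-name hash), so cohorts are reproducible
  from the seed alone and stable under insertion of new devices.

## Numerical choices and degenerate inputs

Missing values are NaN and never remove grid timestamps; re-gridding is
NaN-aware. Zero between-subject variance degrades ICC to 0 with a
warning; zero SD with a nonzero mean difference makes SAD undefined
(raised, not silently zeroed); constant regressors are rejected.
Empirical quantiles interpolate linearly between order statistics.
All-night summaries require ≥3 nights; stage strata under 10 pairs are
reported absent. The time-course trend MAPE excludes hourly bins whose
mean-centered reference magnitude is below ε = 0.05 (raw percentage
errors blow up where the centered trend crosses zero; ε guards only the
near-zero bins).

## Problem sizes in the test suite

The shipped tests run the pipeline at reduced scale — nights of 1–8 h,
cohorts of 2–9 nights, 50–200 replicates for the Monte-Carlo suites —
sizes chosen so the statistical checks (CI coverage, stationary
occupancy, monotonicity counts) retain power while the suite stays quick
to run routinely.

## What the synthetic cohorts do and do not show

Passing tests establish that the statistics are computed correctly (they
match brute-force oracles and closed forms), that the harmonization
recovers injected clock lags, and that the estimators recover known
generator parameters. They do not validate the generator as a model of
real physiology: real RR series have autonomic structure beyond white
jitter, real respiration has amplitude variation and apnea-shaped
morphology, device errors are neither Gaussian nor stationary, and
staging errors are not symmetric. Conclusions about any physical
device's accuracy require real paired recordings; this package supplies
the machinery for that comparison, not the evidence.
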