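"""Synthetic overnight-cohort generator.

Emulates the data an overnight device-validation study collects: a
stage-structured consensus hypnogram (first-order Markov chain over
W / N1 / N2 / N3 / REM / no-presence at 30-s epochs), stage- and
time-dependent reference vital signs (beat timestamps for heart rate, a
frequency-modulated respiration waveform for breathing rate), scored
breathing-disturbance and snore events, and per-device corrupted
observations of the truth.

Each contactless device is described by a parametric observation model
(:class:`DeviceModel`): epoch length, additive bias, Gaussian noise,
output quantization, clipping to the device's reporting range,
wake-epoch missingness, and a clock offset. Presets mirror the three
device families evaluated in the laboratory: an undermattress sensor
reporting integer-rounded values at 60-s epochs (``wsa``), an
undermattress sensor estimating heart rate at 4-s substeps averaged to
30 s (``emfit``), and a bedside radar reporting breathing rate only,
with missing estimates concentrated in wake (``somnofy``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .epochs import (
    ARTIFACT,
    BinarySeries,
    DEVICE_STAGES,
    EXCLUDED_STAGES,
    EpochSeries,
    Hypnogram,
    NO_PRESENCE,
    REFERENCE_STAGES,
    REM,
    WAKE,
    Waveform,
    epoch_grid,
)
from .errors import ConfigurationError, InputError
from .events import APNEA, Event, EventList, HYPOPNEA, SNORE
from .records import DeviceNight, NightRecord

#: Order of states in the stage-transition matrix.
CHAIN_STATES = (WAKE, "N1", "N2", "N3", REM, NO_PRESENCE)

#: Default stage-transition matrix (30-s epochs). Calibrated so that the
#: mean simulated total sleep time of a 10-hour night is ~386 minutes, with
#: realistic stage occupancies (stationary occupancy roughly W 35%, N1 7%,
#: N2 28%, N3 17%, REM 12%, no-presence <1%).
DEFAULT_STAGE_TRANSITION = np.array([
    [0.927, 0.053, 0.010, 0.000, 0.005, 0.005],
    [0.110, 0.590, 0.280, 0.000, 0.020, 0.000],
    [0.030, 0.020, 0.845, 0.060, 0.045, 0.000],
    [0.011, 0.000, 0.092, 0.897, 0.000, 0.000],
    [0.050, 0.030, 0.050, 0.000, 0.870, 0.000],
    [0.300, 0.000, 0.000, 0.000, 0.000, 0.700],
])

#: Stage-dependent vital-sign levels (bpm / cpm). Occupancy-weighted means
#: under the default transition matrix reproduce the cohort-level laboratory
#: averages of ~62 bpm and ~15 cpm.
DEFAULT_HR_STAGE_MEANS = {WAKE: 66.0, "N1": 63.0, "N2": 61.0, "N3": 59.0, REM: 64.0}
DEFAULT_BR_STAGE_MEANS = {WAKE: 15.5, "N1": 15.0, "N2": 14.5, "N3": 14.0, REM: 15.2}


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults encode the study conditions: a 10-hour time in bed scored at
    30-s epochs, cohort mean overnight heart rate 62.2 bpm with a
    between-participant SD of 8.9 bpm, mean breathing rate 14.7 cpm with
    SD 2.9 cpm, snore scoring against a dB intensity trace, and
    apnea/hypopnea events at ``ahi_rate`` per hour of sleep.
    """

    n_participants: int = 35
    night_duration_s: float = 36000.0
    epoch_s: float = 30.0
    stage_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAGE_TRANSITION.copy())
    hr_stage_means: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HR_STAGE_MEANS))
    br_stage_means: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BR_STAGE_MEANS))
    hr_trend_amplitude: float = 3.0
    br_trend_amplitude: float = 0.5
    hr_between_sd: float = 8.9
    br_between_sd: float = 2.9
    hrv_sd: float = 0.05
    resp_noise_sd: float = 0.1
    ahi_rate: float = 10.0
    snore_propensity: float = 0.10
    snore_intensity_mean_db: float = 45.0
    snore_intensity_sd_db: float = 6.0
    resp_fs: float = 8.0
    snore_fs: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_transition = np.asarray(self.stage_transition, dtype=float)
        if self.stage_transition.shape != (6, 6):
            raise ConfigurationError("stage_transition must be a 6x6 matrix")
        row_sums = self.stage_transition.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-12) or np.any(self.stage_transition < 0):
            raise ConfigurationError("stage_transition rows must be probability vectors"
                                     " summing to 1 within 1e-12")
        for name in ("hrv_sd", "resp_noise_sd", "ahi_rate", "snore_propensity",
                     "snore_intensity_sd_db", "hr_between_sd", "br_between_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.snore_propensity <= 1.0):
            raise ConfigurationError("snore_propensity must be a probability")
        n_epochs = self.night_duration_s / self.epoch_s
        if abs(n_epochs - round(n_epochs)) > 1e-9 or n_epochs < 1:
            raise ConfigurationError("epoch_s must divide night_duration_s")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")

    @property
    def n_epochs(self) -> int:
        return int(round(self.night_duration_s / self.epoch_s))


@dataclass
class DeviceModel:
    """Parametric observation model for one contactless device.

    The device observes the per-epoch truth through
    ``clip(quantize(true + bias + Normal(0, noise_sd)))`` on its own epoch
    grid, drops wake epochs with probability ``wake_missing_prob``, and
    reports timestamps offset by ``clock_lag_s``. Quantization rounds
    half away from zero. ``hr_substep_s`` models devices that estimate
    heart rate at a finer step and average it to 30 s (noise is then drawn
    per substep, so the per-epoch noise SD is ``noise_sd_hr / sqrt(m)`` for
    ``m`` substeps per epoch).
    """

    name: str
    reports_hr: bool = True
    reports_br: bool = True
    epoch_s: float = 30.0
    hr_substep_s: Optional[float] = None
    bias_hr: float = 0.0
    bias_br: float = 0.0
    noise_sd_hr: float = 0.0
    noise_sd_br: float = 0.0
    rounding_quantum: float = 0.0
    hr_clip: Optional[Tuple[float, float]] = None
    br_clip: Optional[Tuple[float, float]] = None
    wake_missing_prob: float = 0.0
    clock_lag_s: float = 0.0
    stage_accuracy: float = 0.9
    reports_snore: bool = False
    snore_detect_threshold_db: float = 42.0
    snore_detect_noise_db: float = 3.0
    reports_ahi: bool = False
    reports_bdi: bool = False
    ahi_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for clip in (self.hr_clip, self.br_clip):
            if clip is not None and not clip[0] < clip[1]:
                raise ConfigurationError("clip range must satisfy min < max")
        if not (0.0 <= self.wake_missing_prob <= 1.0):
            raise ConfigurationError("wake_missing_prob must be in [0, 1]")
        if abs(self.clock_lag_s) > 300:
            raise ConfigurationError("|clock_lag_s| must be <= 300 s")
        if self.epoch_s not in (30.0, 60.0, 30, 60):
            raise ConfigurationError("device epoch_s must be 30 or 60 s")
        if not (0.0 <= self.stage_accuracy <= 1.0):
            raise ConfigurationError("stage_accuracy must be in [0, 1]")


def wsa_model(**overrides) -> DeviceModel:
    """Undermattress sensor: 60-s epochs, integer-rounded outputs,
    HR reported in [40, 90] bpm and BR in [8, 35] cpm; also reports a
    per-epoch snore flag and a breathing disorder index (BDI)."""
    params = dict(name="wsa", epoch_s=60.0, rounding_quantum=1.0,
                  hr_clip=(40.0, 90.0), br_clip=(8.0, 35.0),
                  bias_hr=-0.4, bias_br=-0.9, noise_sd_hr=2.5, noise_sd_br=1.5,
                  reports_snore=True, reports_bdi=True, ahi_noise_sd=4.0)
    params.update(overrides)
    return DeviceModel(**params)


def emfit_model(**overrides) -> DeviceModel:
    """Undermattress sensor: HR estimated at 4-s substeps averaged to 30 s,
    HR reported in [40, 135] bpm and BR in [6, 30] cpm."""
    params = dict(name="emfit", epoch_s=30.0, hr_substep_s=4.0,
                  hr_clip=(40.0, 135.0), br_clip=(6.0, 30.0),
                  bias_hr=0.45, bias_br=-0.15, noise_sd_hr=7.5, noise_sd_br=1.6)
    params.update(overrides)
    return DeviceModel(**params)


def somnofy_model(**overrides) -> DeviceModel:
    """Bedside radar: breathing rate only at 30-s epochs, BR in [6, 30] cpm,
    with missing estimates concentrated in device-scored wake."""
    params = dict(name="somnofy", reports_hr=False, epoch_s=30.0,
                  br_clip=(6.0, 30.0), bias_br=-0.5, noise_sd_br=1.4,
                  wake_missing_prob=0.6)
    params.update(overrides)
    return DeviceModel(**params)


DEVICE_PRESETS = {"wsa": wsa_model, "emfit": emfit_model, "somnofy": somnofy_model}


def round_to_quantum(values: np.ndarray, quantum: float) -> np.ndarray:
    """Quantize to multiples of ``quantum``, rounding half away from zero.

    ``quantum == 0`` means no quantization. NaNs pass through.
    """
    if quantum == 0:
        return np.asarray(values, dtype=float)
    v = np.asarray(values, dtype=float)
    return np.sign(v) * np.floor(np.abs(v) / quantum + 0.5) * quantum


def simulate_hypnogram(config: SimulationConfig, seed: int) -> Hypnogram:
    """Sample a consensus hypnogram from the first-order stage chain.

    The night starts in wake (lights off with the participant awake);
    subsequent 30-s epochs follow ``config.stage_transition``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_epochs
    cum = np.cumsum(config.stage_transition, axis=1)
    states = np.empty(n, dtype=int)
    states[0] = 0  # wake
    u = rng.random(n)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    labels = np.array(CHAIN_STATES, dtype=object)[states]
    grid = epoch_grid(config.night_duration_s, config.epoch_s)
    return Hypnogram(grid, labels, config.epoch_s, vocabulary=REFERENCE_STAGES)


def _nocturnal_trend(u: np.ndarray, amplitude: float,
                     trough_frac: float = 0.75) -> np.ndarray:
    """Overnight modulation: starts at +A/2, decreases monotonically to its
    minimum (-A/2) at ``trough_frac`` of the night, then rises modestly
    toward the end — the characteristic decline-then-uptick of nocturnal
    heart rate."""
    u = np.asarray(u, dtype=float)
    down = 0.5 * amplitude * np.cos(np.pi * np.minimum(u, trough_frac) / trough_frac)
    up = np.where(u > trough_frac,
                  0.25 * amplitude * (u - trough_frac) / max(1e-12, 1 - trough_frac),
                  0.0)
    return down + up


def _stage_level(hypnogram: Hypnogram, stage_means: Dict[str, float]) -> np.ndarray:
    """Per-epoch stage-dependent level; bookkeeping labels fall back to the
    wake level (the participant's physiology does not pause with scoring)."""
    return np.array([stage_means.get(s, stage_means[WAKE]) for s in hypnogram.stages],
                    dtype=float)


def true_vitals_series(hypnogram: Hypnogram, config: SimulationConfig,
                       hr_offset: float = 0.0, br_offset: float = 0.0
                       ) -> Tuple[EpochSeries, EpochSeries]:
    """Noise-free per-epoch target heart and breathing rate.

    value = stage mean + overnight trend (at the epoch midpoint) +
    per-participant offset.
    """
    mid = hypnogram.epoch_start_s + hypnogram.epoch_s / 2
    u = (mid - hypnogram.epoch_start_s[0]) / (len(hypnogram) * hypnogram.epoch_s)
    hr = (_stage_level(hypnogram, config.hr_stage_means) + hr_offset
          + _nocturnal_trend(u, config.hr_trend_amplitude))
    br = (_stage_level(hypnogram, config.br_stage_means) + br_offset
          + _nocturnal_trend(u, config.br_trend_amplitude))
    grid = hypnogram.epoch_start_s.copy()
    return (EpochSeries(grid, hr, hypnogram.epoch_s, unit="bpm"),
            EpochSeries(grid.copy(), br, hypnogram.epoch_s, unit="cpm"))


def simulate_reference_vitals(hypnogram: Hypnogram, config: SimulationConfig,
                              seed: int, hr_offset: float = 0.0,
                              br_offset: float = 0.0
                              ) -> Tuple[np.ndarray, Waveform, EpochSeries, EpochSeries]:
    """Emit reference signals consistent with the hypnogram.

    Returns ``(beat_timestamps, respiration_waveform, true_hr, true_br)``:
    beats with RR = 60/HR(t) plus Gaussian jitter of SD ``hrv_sd``; a
    respiration trace as a frequency-modulated unit sinusoid at the
    instantaneous breathing rate plus additive noise; and the noise-free
    per-epoch targets.
    """
    rng = np.random.default_rng(seed)
    true_hr, true_br = true_vitals_series(hypnogram, config, hr_offset, br_offset)
    t0 = hypnogram.epoch_start_s[0]
    duration = len(hypnogram) * hypnogram.epoch_s
    epoch_s = hypnogram.epoch_s
    n_ep = len(hypnogram)

    # Beats: step-function instantaneous HR per epoch.
    hr_values = true_hr.values
    beats = []
    t = t0
    while t < t0 + duration:
        idx = min(int((t - t0) // epoch_s), n_ep - 1)
        rr = 60.0 / max(hr_values[idx], 20.0)
        if config.hrv_sd > 0:
            rr = max(0.25, rr + rng.normal(0.0, config.hrv_sd))
        t += rr
        if t < t0 + duration:
            beats.append(t)
    beats = np.array(beats, dtype=float)

    # Respiration: phase-integrated FM oscillation.
    fs = config.resp_fs
    n_samp = int(round(duration * fs))
    sample_epoch = np.minimum((np.arange(n_samp) / fs // epoch_s).astype(int), n_ep - 1)
    inst_br = true_br.values[sample_epoch]
    phase = np.cumsum(2.0 * np.pi * inst_br / 60.0 / fs)
    wave = np.sin(phase)
    if config.resp_noise_sd > 0:
        wave = wave + rng.normal(0.0, config.resp_noise_sd, n_samp)
    respiration = Waveform(fs=fs, values=wave, start_s=t0)
    return beats, respiration, true_hr, true_br


def simulate_events(hypnogram: Hypnogram, config: SimulationConfig, seed: int
                    ) -> Tuple[EventList, Waveform]:
    """Place respiratory and snore events in sleep epochs.

    Apnea/hypopnea events arrive as a Poisson process with rate
    ``ahi_rate`` per hour of sleep; each lands fully inside a uniformly
    chosen sleep epoch. Snoring is per-epoch Bernoulli with probability
    ``snore_propensity``; intensities are Normal(mean, sd) in dB. The
    returned intensity trace is 0 dB outside snore events.
    """
    rng = np.random.default_rng(seed)
    sleep_idx = np.flatnonzero(hypnogram.is_sleep())
    epoch_s = hypnogram.epoch_s
    duration = len(hypnogram) * epoch_s
    events: List[Event] = []

    if sleep_idx.size and config.ahi_rate > 0:
        sleep_hours = sleep_idx.size * epoch_s / 3600.0
        n_resp = rng.poisson(config.ahi_rate * sleep_hours)
        for _ in range(n_resp):
            ep = rng.choice(sleep_idx)
            dur = rng.uniform(10.0, 25.0)
            start = hypnogram.epoch_start_s[ep] + rng.uniform(0.0, epoch_s - dur)
            kind = APNEA if rng.random() < 0.5 else HYPOPNEA
            events.append(Event(kind, start, dur))

    if sleep_idx.size and config.snore_propensity > 0:
        snoring = sleep_idx[rng.random(sleep_idx.size) < config.snore_propensity]
        for ep in snoring:
            dur = rng.uniform(5.0, 25.0)
            start = hypnogram.epoch_start_s[ep] + rng.uniform(0.0, epoch_s - dur)
            level = rng.normal(config.snore_intensity_mean_db,
                               config.snore_intensity_sd_db)
            events.append(Event(SNORE, start, dur, intensity_db=max(1.0, level)))

    event_list = EventList(events, night_duration_s=duration)
    trace = snore_trace_from_events(event_list, duration, config.snore_fs,
                                    start_s=hypnogram.epoch_start_s[0])
    return event_list, trace


def snore_trace_from_events(events: EventList, duration_s: float, fs: float,
                            start_s: float = 0.0) -> Waveform:
    """Render snore events into a sampled dB intensity trace (0 outside)."""
    n = int(round(duration_s * fs))
    values = np.zeros(n)
    for ev in events.snores:
        i0 = max(0, int(np.ceil((ev.start_s - start_s) * fs)))
        i1 = min(n, int(np.floor((ev.end_s - start_s) * fs)) + 1)
        if i1 > i0:
            values[i0:i1] = np.maximum(values[i0:i1], ev.intensity_db)
    return Waveform(fs=fs, values=values, start_s=start_s)


def _regrid_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean of consecutive blocks of ``factor`` values, NaN-aware."""
    n_out = values.size // factor
    block = values[: n_out * factor].reshape(n_out, factor)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(block, axis=1)
    return out


def device_hypnogram_from_reference(hypnogram: Hypnogram, model: DeviceModel,
                                    rng: np.random.Generator) -> Hypnogram:
    """Reference staging as the device would report it: mapped to the
    4-state vocabulary, re-gridded to the device epoch, with symmetric
    label confusion at rate ``1 - stage_accuracy`` among the four stages."""
    dev = hypnogram.to_device_vocabulary()
    factor = int(round(model.epoch_s / hypnogram.epoch_s))
    if factor > 1:
        stages = dev.stages[::factor].copy()
        grid = dev.epoch_start_s[::factor].copy()
    else:
        stages = dev.stages.copy()
        grid = dev.epoch_start_s.copy()
    scorable = ~np.isin(stages, list(EXCLUDED_STAGES))
    if model.stage_accuracy < 1.0:
        flip = scorable & (rng.random(stages.size) > model.stage_accuracy)
        four = np.array([WAKE, "LS", "DS", REM], dtype=object)
        for i in np.flatnonzero(flip):
            others = four[four != stages[i]]
            stages[i] = rng.choice(others)
    return Hypnogram(grid, stages, model.epoch_s, vocabulary=DEVICE_STAGES)


def apply_device_model(true_hr: Optional[EpochSeries], true_br: Optional[EpochSeries],
                       hypnogram: Hypnogram, model: DeviceModel, seed: int
                       ) -> Tuple[Optional[EpochSeries], Optional[EpochSeries], Hypnogram]:
    """Corrupt the noise-free truth through one device's observation model.

    Observed value = clip(quantize(true + bias + noise)) on the device's
    epoch grid; wake epochs (per the device hypnogram) are dropped with
    ``wake_missing_prob``; all timestamps are shifted by ``clock_lag_s``.
    """
    rng = np.random.default_rng(seed)
    dev_hyp = device_hypnogram_from_reference(hypnogram, model, rng)
    wake_mask = dev_hyp.stages == WAKE
    drop = wake_mask & (rng.random(len(dev_hyp)) < model.wake_missing_prob)

    def observe(true: EpochSeries, bias: float, noise_sd: float,
                clip: Optional[Tuple[float, float]], unit: str,
                substep_s: Optional[float]) -> EpochSeries:
        factor = int(round(model.epoch_s / true.epoch_s))
        if abs(factor * true.epoch_s - model.epoch_s) > 1e-9 or factor < 1:
            raise InputError("device epoch_s must be a multiple of the truth grid")
        if substep_s is not None:
            # Finer-step estimation averaged back to the truth grid: noise
            # is drawn per substep so per-epoch noise SD shrinks by sqrt(m).
            m = max(1, int(round(true.epoch_s / substep_s)))
            noise = rng.normal(0.0, noise_sd, (len(true), m)).mean(axis=1) \
                if noise_sd > 0 else 0.0
            values = true.values + bias + noise
            grid = true.epoch_start_s.copy()
            if factor > 1:
                values = _regrid_mean(values, factor)
                grid = grid[::factor][: values.size]
        else:
            if factor > 1:
                values = _regrid_mean(true.values, factor)
                grid = true.epoch_start_s[::factor][: values.size].copy()
            else:
                values = true.values.copy()
                grid = true.epoch_start_s.copy()
            if noise_sd > 0:
                values = values + rng.normal(0.0, noise_sd, values.size)
            values = values + bias
        values = round_to_quantum(values, model.rounding_quantum)
        if clip is not None:
            values = np.clip(values, clip[0], clip[1])
        n = min(values.size, drop.size)
        values = values[:n].astype(float)
        values[drop[:n]] = np.nan
        return EpochSeries(grid[:n] + model.clock_lag_s, values, model.epoch_s, unit=unit)

    device_hr = None
    device_br = None
    if model.reports_hr and true_hr is not None:
        device_hr = observe(true_hr, model.bias_hr, model.noise_sd_hr,
                            model.hr_clip, "bpm", model.hr_substep_s)
    if model.reports_br and true_br is not None:
        device_br = observe(true_br, model.bias_br, model.noise_sd_br,
                            model.br_clip, "cpm", None)
    return device_hr, device_br, dev_hyp.shift(model.clock_lag_s)


def _stream(seed: int, participant: int, channel: int, extra: int = 0
            ) -> np.random.Generator:
    """Counter-based sub-seeding: independent streams keyed by (master seed,
    participant index, channel code, extra key), stable under the insertion
    of new devices because device streams are keyed by a name hash."""
    return np.random.default_rng([seed & 0x7FFFFFFF, participant, channel, extra])


def _device_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def device_snore_epochs(events: EventList, hypnogram: Hypnogram, model: DeviceModel,
                        rng: np.random.Generator) -> BinarySeries:
    """Device per-epoch snore flags: an epoch is flagged when it overlaps a
    snore event whose intensity, perturbed by detection noise, exceeds the
    device threshold — quieter snores are preferentially missed."""
    grid = hypnogram.epoch_start_s
    epoch_s = hypnogram.epoch_s
    flags = np.zeros(grid.size, dtype=bool)
    for ev in events.snores:
        perceived = ev.intensity_db + rng.normal(0.0, model.snore_detect_noise_db)
        if perceived < model.snore_detect_threshold_db:
            continue
        first = int(np.floor((ev.start_s - grid[0]) / epoch_s))
        last = int(np.floor((ev.end_s - 1e-9 - grid[0]) / epoch_s))
        for i in range(max(0, first), min(grid.size - 1, last) + 1):
            flags[i] = True
    return BinarySeries(grid.copy(), flags, epoch_s)


def simulate_night(config: SimulationConfig, device_models: Sequence[DeviceModel],
                   seed: int, participant: int) -> NightRecord:
    """Generate one participant-night with all configured device channels."""
    hyp = simulate_hypnogram(config, _stream(seed, participant, 0).integers(2**31))
    offs_rng = _stream(seed, participant, 1)
    hr_offset = offs_rng.normal(0.0, config.hr_between_sd)
    br_offset = offs_rng.normal(0.0, config.br_between_sd)
    vit_seed = _stream(seed, participant, 2).integers(2**31)
    beats, respiration, true_hr, true_br = simulate_reference_vitals(
        hyp, config, int(vit_seed), hr_offset=hr_offset, br_offset=br_offset)
    ev_seed = _stream(seed, participant, 3).integers(2**31)
    events, snore_trace = simulate_events(hyp, config, int(ev_seed))

    from .reference import compute_ahi  # local import to avoid a cycle
    tst_s = hyp.total_sleep_time_s()
    ref_ahi = compute_ahi(events, tst_s) if tst_s > 0 else 0.0

    record = NightRecord(
        participant_id=f"p{participant:03d}",
        setting="lab",
        beats_s=beats,
        respiration=respiration,
        hypnogram=hyp,
        snore_trace=snore_trace,
        events=events,
        lights_off_s=0.0,
        lights_on_s=config.night_duration_s,
        metadata={"ahi_reference": ref_ahi, "arrhythmia_flag": False,
                  "hr_offset": hr_offset, "br_offset": br_offset},
    )
    for model in device_models:
        drng = _stream(seed, participant, 4, _device_key(model.name))
        dev_hr, dev_br, dev_hyp = apply_device_model(
            true_hr, true_br, hyp, model, int(drng.integers(2**31)))
        night = DeviceNight(device=model.name, hr=dev_hr, br=dev_br,
                            hypnogram=dev_hyp)
        if model.reports_snore:
            night.snore_epochs = device_snore_epochs(events, hyp, model, drng)
        if model.reports_bdi or model.reports_ahi:
            dev_ahi = max(0.0, ref_ahi + drng.normal(0.0, model.ahi_noise_sd))
            if model.reports_ahi:
                night.ahi = dev_ahi
            if model.reports_bdi:
                night.bdi = 2.0 * dev_ahi
        record.devices[model.name] = night
    return record


def make_cohort(config: SimulationConfig, device_models: Sequence[DeviceModel],
                seed: int) -> List[NightRecord]:
    """Generate ``config.n_participants`` independent participant-nights.

    Per-participant sub-seeds are derived deterministically from the master
    seed, so the same seed always yields the same cohort and adding a device
    does not disturb the reference channels or other devices.
    """
    return [simulate_night(config, device_models, seed, i)
            for i in range(config.n_participants)]
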