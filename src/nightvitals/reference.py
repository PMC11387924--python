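"""Reference vital-sign extraction from polysomnography-side records.

Heart rate comes from beat timestamps (interval-mean of instantaneous
rates per 30-s epoch), breathing rate from inspiratory-peak intervals in
the respiration band signal, snoring from a dB intensity trace
thresholded at 30 dB with a 300-ms minimum duration, and the
apnea-hypopnea index (AHI) from the scored event list divided by total
sleep time. These are transparent re-implementations of the standard
extraction steps — functionally, not bit-for-bit, equivalent to the
toolbox chains a sleep laboratory would run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sp_signal

from .epochs import EpochSeries, Waveform, epoch_grid
from .errors import InputError, UndefinedResultError
from .events import Event, EventList, SNORE

#: Snore scoring defaults: amplitude threshold and minimum episode duration.
SNORE_THRESHOLD_DB = 30.0
SNORE_MIN_DURATION_S = 0.3

#: AHI severity bins (events/hour): <5 normal, 5-<15 mild, 15-<30 moderate,
#: >=30 severe. Boundary values fall in the higher class.
AHI_SEVERITY_BINS = ((5.0, "normal"), (15.0, "mild"), (30.0, "moderate"))
AHI_SEVERITY_LABELS = ("normal", "mild", "moderate", "severe")


def hr_from_beats(beats_s: np.ndarray, grid_start_s: float, n_epochs: int,
                  epoch_s: float = 30.0) -> EpochSeries:
    """Per-epoch heart rate from beat timestamps.

    Each beat-to-beat interval contributes an instantaneous rate 60/RR
    assigned to the epoch containing the interval's *ending* beat; the
    epoch value is the mean of its contributing rates. Epochs with fewer
    than two beats are reported missing — a rate needs at least one
    interval ending locally.

    Parameters
    ----------
    beats_s : array of float
        Strictly increasing beat timestamps in seconds.
    grid_start_s, n_epochs, epoch_s :
        The output epoch grid (left edges, half-open intervals).
    """
    beats = np.asarray(beats_s, dtype=float)
    if beats.size < 2:
        raise InputError("need at least 2 beats")
    if np.any(np.diff(beats) <= 0):
        raise InputError("beat timestamps must be strictly increasing")
    rr = np.diff(beats)
    rates = 60.0 / rr
    end_beats = beats[1:]
    idx = np.floor((end_beats - grid_start_s) / epoch_s).astype(int)
    beat_idx = np.floor((beats - grid_start_s) / epoch_s).astype(int)

    values = np.full(n_epochs, np.nan)
    in_range = (idx >= 0) & (idx < n_epochs)
    sums = np.bincount(idx[in_range], weights=rates[in_range], minlength=n_epochs)
    counts = np.bincount(idx[in_range], minlength=n_epochs)
    beats_per_epoch = np.bincount(beat_idx[(beat_idx >= 0) & (beat_idx < n_epochs)],
                                  minlength=n_epochs)
    ok = (counts > 0) & (beats_per_epoch >= 2)
    values[ok] = sums[ok] / counts[ok]
    grid = grid_start_s + epoch_s * np.arange(n_epochs, dtype=float)
    return EpochSeries(grid, values, epoch_s, unit="bpm")


def br_from_respiration(waveform: Waveform, grid_start_s: float, n_epochs: int,
                        epoch_s: float = 30.0, min_peak_separation_s: float = 1.5,
                        prominence_frac: float = 0.25) -> EpochSeries:
    """Per-epoch breathing rate from inspiratory peaks of a band signal.

    The trace is detrended, inspiratory peaks are detected with a minimum
    separation of ``min_peak_separation_s`` and a prominence of at least
    ``prominence_frac`` times the interquartile amplitude of the epoch the
    peak falls in, and each breath-to-breath interval contributes an
    instantaneous rate 60/interval to the epoch containing its ending
    peak. Epochs with fewer than two peaks are missing; a flat signal
    yields all-missing values, not an exception.
    """
    if waveform.fs < 4:
        raise InputError("respiration sampling rate must be >= 4 Hz")
    x = sp_signal.detrend(waveform.values, type="linear")
    distance = max(1, int(round(min_peak_separation_s * waveform.fs)))
    peaks, props = sp_signal.find_peaks(x, distance=distance, prominence=0.0)
    if peaks.size:
        peak_t = waveform.start_s + peaks / waveform.fs
        peak_epoch = np.floor((peak_t - grid_start_s) / epoch_s).astype(int)
        # per-epoch interquartile amplitude -> per-peak prominence threshold
        sample_epoch = np.floor(
            (waveform.times_s - grid_start_s) / epoch_s).astype(int)
        thresh = np.zeros(peaks.size)
        for ep in np.unique(peak_epoch):
            if ep < 0 or ep >= n_epochs:
                continue
            seg = x[sample_epoch == ep]
            iqr = float(np.subtract(*np.percentile(seg, [75, 25]))) if seg.size else 0.0
            thresh[peak_epoch == ep] = prominence_frac * iqr
        keep = props["prominences"] >= thresh
        peaks = peaks[keep]

    grid = grid_start_s + epoch_s * np.arange(n_epochs, dtype=float)
    values = np.full(n_epochs, np.nan)
    if peaks.size >= 2:
        peak_t = waveform.start_s + peaks / waveform.fs
        intervals = np.diff(peak_t)
        rates = 60.0 / intervals
        end_idx = np.floor((peak_t[1:] - grid_start_s) / epoch_s).astype(int)
        peak_idx = np.floor((peak_t - grid_start_s) / epoch_s).astype(int)
        in_range = (end_idx >= 0) & (end_idx < n_epochs)
        sums = np.bincount(end_idx[in_range], weights=rates[in_range],
                           minlength=n_epochs)
        counts = np.bincount(end_idx[in_range], minlength=n_epochs)
        peaks_per_epoch = np.bincount(
            peak_idx[(peak_idx >= 0) & (peak_idx < n_epochs)], minlength=n_epochs)
        ok = (counts > 0) & (peaks_per_epoch >= 2)
        values[ok] = sums[ok] / counts[ok]
    return EpochSeries(grid, values, epoch_s, unit="cpm")


def score_snore(intensity_trace: Waveform,
                amplitude_threshold_db: float = SNORE_THRESHOLD_DB,
                min_duration_s: float = SNORE_MIN_DURATION_S,
                epoch_s: float = 30.0,
                n_epochs: Optional[int] = None
                ) -> Tuple[EventList, np.ndarray]:
    """Score snore events from a dB intensity trace.

    Maximal runs of samples strictly above ``amplitude_threshold_db``
    lasting at least ``min_duration_s`` become events; the per-epoch binary
    marks epochs overlapping any event.
    """
    x = intensity_trace.values
    fs = intensity_trace.fs
    above = x > amplitude_threshold_db
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    events = []
    for s, e in zip(starts, ends):
        dur = (e - s) / fs
        if dur + 1e-12 >= min_duration_s:
            level = float(np.mean(x[s:e]))
            events.append(Event(SNORE, intensity_trace.start_s + s / fs, dur,
                                intensity_db=level))
    if n_epochs is None:
        n_epochs = int(np.ceil(intensity_trace.duration_s / epoch_s))
    ev_list = EventList(events)
    binary = np.zeros(n_epochs, dtype=bool)
    g0 = intensity_trace.start_s
    for ev in events:
        first = int(np.floor((ev.start_s - g0) / epoch_s))
        last = int(np.floor((ev.end_s - 1e-9 - g0) / epoch_s))
        binary[max(0, first): min(n_epochs - 1, last) + 1] = True
    return ev_list, binary


def compute_ahi(events: EventList, total_sleep_time_s: float) -> float:
    """Apnea-hypopnea index: respiratory events per hour of sleep."""
    if total_sleep_time_s <= 0:
        raise UndefinedResultError("AHI undefined for zero total sleep time")
    n = len(events.respiratory)
    return n / (total_sleep_time_s / 3600.0)


def classify_ahi_severity(ahi: float) -> str:
    """Severity label for an AHI value; boundaries go to the higher class."""
    if ahi < 0:
        raise InputError("AHI must be non-negative")
    for upper, label in AHI_SEVERITY_BINS:
        if ahi < upper:
            return label
    return "severe"


@dataclass
class BreathingDisturbanceSummary:
    """Night-level breathing-disturbance indices."""

    ahi: float
    bdi: Optional[float]
    snore_duration_min: float
    severity: str

    def __post_init__(self) -> None:
        if self.ahi < 0 or self.snore_duration_min < 0:
            raise InputError("ahi and snore_duration_min must be >= 0")
        if self.severity != classify_ahi_severity(self.ahi):
            raise InputError("severity label inconsistent with AHI thresholds")


def summarize_breathing(events: EventList, total_sleep_time_s: float,
                        bdi: Optional[float] = None) -> BreathingDisturbanceSummary:
    """Bundle AHI, optional BDI, merged snore minutes and severity class."""
    ahi = compute_ahi(events, total_sleep_time_s)
    snore_min = events.snores.total_duration_s() / 60.0
    return BreathingDisturbanceSummary(ahi=ahi, bdi=bdi,
                                       snore_duration_min=snore_min,
                                       severity=classify_ahi_severity(ahi))
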