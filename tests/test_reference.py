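"""Reference extraction: HR from beats, BR from respiration, snore, AHI."""

import numpy as np
import pytest

from nightvitals import (
    InputError,
    UndefinedResultError,
    Waveform,
    br_from_respiration,
    classify_ahi_severity,
    compute_ahi,
    hr_from_beats,
    score_snore,
)
from nightvitals.events import APNEA, Event, EventList, HYPOPNEA
from nightvitals.reference import summarize_breathing


class TestHrFromBeats:
    @pytest.mark.parametrize("rr, expected", [(1.0, 60.0), (0.75, 80.0)])
    def test_constant_rr(self, rr, expected):
        beats = np.arange(0.0, 30.0 + rr / 2, rr)
        series = hr_from_beats(beats, 0.0, 1)
        assert series.values[0] == pytest.approx(expected)

    def test_irregular_intervals_average_instantaneous_rates(self):
        # RRs 1.0, 0.5, 1.0, 0.5 -> rates 60, 120, 60, 120 -> mean 90,
        # identical to enumerating the intervals by hand
        beats = np.array([0.0, 1.0, 1.5, 2.5, 3.0])
        series = hr_from_beats(beats, 0.0, 1)
        by_hand = np.mean([60 / rr for rr in np.diff(beats)])
        assert series.values[0] == pytest.approx(90.0) == pytest.approx(by_hand)

    def test_unsorted_beats_rejected(self):
        with pytest.raises(InputError):
            hr_from_beats(np.array([0.0, 2.0, 1.0]), 0.0, 1)

    def test_sparse_epochs_are_missing(self):
        # second epoch holds a single beat: no local rate
        beats = np.array([0.0, 1.0, 2.0, 3.0, 45.0])
        series = hr_from_beats(beats, 0.0, 2)
        assert np.isnan(series.values[1])

    def test_known_constant_hr_recovered(self):
        """Beats generated at a constant 72 bpm are recovered exactly with
        zero jitter, and within 3 SE with jitter."""
        rr = 60.0 / 72.0
        beats = np.arange(0.0, 300.0, rr)
        series = hr_from_beats(beats, 0.0, 10)
        assert np.allclose(series.values, 72.0, atol=1e-9)

        rng = np.random.default_rng(1)
        jitter = rng.normal(0.0, 0.02, beats.size)
        noisy = np.sort(beats + jitter)
        series_j = hr_from_beats(noisy, 0.0, 10)
        se = np.nanstd(series_j.values, ddof=1) / np.sqrt(10)
        assert abs(np.nanmean(series_j.values) - 72.0) <= max(3 * se, 1.0)


def _sine_wave(freq_hz, duration_s=300.0, fs=8.0, amp=1.0):
    t = np.arange(0.0, duration_s, 1.0 / fs)
    return Waveform(fs=fs, values=amp * np.sin(2 * np.pi * freq_hz * t))


class TestBrFromRespiration:
    @pytest.mark.parametrize("freq, cpm", [(0.25, 15.0), (0.1, 6.0)])
    def test_pure_sinusoid(self, freq, cpm):
        wave = _sine_wave(freq)
        series = br_from_respiration(wave, 0.0, 10)
        assert np.allclose(series.values, cpm, atol=0.15)

    def test_flat_signal_yields_missing_not_error(self):
        wave = Waveform(fs=8.0, values=np.zeros(8 * 120))
        series = br_from_respiration(wave, 0.0, 4)
        assert np.all(np.isnan(series.values))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(InputError):
            br_from_respiration(Waveform(fs=2.0, values=np.zeros(100)), 0.0, 1)

    def test_fm_ramp_recovered_within_1cpm(self):
        """A frequency-modulated waveform ramping 10 -> 20 cpm is
        recovered within 1 cpm per epoch (generator truth as oracle)."""
        fs, duration = 8.0, 600.0
        n = int(duration * fs)
        t = np.arange(n) / fs
        true_cpm = 10.0 + 10.0 * t / duration
        phase = np.cumsum(2 * np.pi * true_cpm / 60.0 / fs)
        wave = Waveform(fs=fs, values=np.sin(phase))
        series = br_from_respiration(wave, 0.0, int(duration // 30))
        epoch_truth = true_cpm.reshape(-1, int(30 * fs)).mean(axis=1)
        ok = ~np.isnan(series.values)
        assert ok.sum() >= len(series) - 2
        assert np.all(np.abs(series.values[ok] - epoch_truth[ok]) <= 1.0)

    def test_agrees_with_zero_crossing_counter(self):
        """Peak-interval extraction and an independent zero-crossing cycle
        counter agree within 1 cpm on a noise-free waveform."""
        wave = _sine_wave(0.2, duration_s=600.0)
        series = br_from_respiration(wave, 0.0, 20)
        x = wave.values
        up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        cpm_oracle = (up.size / 600.0) * 60.0
        assert np.all(np.abs(series.values[~np.isnan(series.values)]
                             - cpm_oracle) <= 1.0)


class TestScoreSnore:
    def test_silent_trace(self):
        trace = Waveform(fs=100.0, values=np.zeros(3000))
        events, binary = score_snore(trace)
        assert len(events) == 0 and not binary.any()

    def test_short_burst_below_min_duration(self):
        values = np.zeros(1000)
        values[100:120] = 40.0  # 0.2 s at 100 Hz
        events, _ = score_snore(Waveform(fs=100.0, values=values))
        assert len(events) == 0

    def test_amplitude_and_duration_rules_combine(self):
        # 0.5 s at 35 dB passes both rules; 1.0 s at 29 dB fails amplitude
        values = np.zeros(3000)
        values[100:150] = 35.0
        values[1000:1100] = 29.0
        events, binary = score_snore(Waveform(fs=100.0, values=values))
        assert len(events) == 1
        assert events.events[0].duration_s == pytest.approx(0.5, abs=0.02)
        assert binary[0]

    def test_duration_invariant_to_upsampling(self):
        """Factor-of-2 upsampling changes total scored duration by less
        than one sample period."""
        rng = np.random.default_rng(3)
        values = np.where(rng.random(2000) < 0.1, 40.0, 0.0)
        # smear to create multi-sample runs
        values = np.maximum(values, np.roll(values, 1))
        coarse = Waveform(fs=50.0, values=values)
        fine = Waveform(fs=100.0, values=np.repeat(values, 2))
        ev_c, _ = score_snore(coarse)
        ev_f, _ = score_snore(fine)
        assert abs(ev_c.total_duration_s() - ev_f.total_duration_s()) < 1.0 / 50.0


class TestAhi:
    def test_zero_events(self):
        assert compute_ahi(EventList([]), 6 * 3600.0) == 0.0

    def test_events_per_hour(self):
        events = EventList([Event(APNEA, 10.0 * i, 10.0) for i in range(120)])
        assert compute_ahi(events, 6 * 3600.0) == pytest.approx(20.0)

    def test_example_participant_value(self):
        # 145 events over 6.017 h of sleep -> AHI 24.1 (moderate apnea)
        events = EventList([Event(HYPOPNEA, 100.0 * i, 10.0) for i in range(145)])
        ahi = compute_ahi(events, 6.017 * 3600.0)
        assert round(ahi, 1) == 24.1
        assert classify_ahi_severity(ahi) == "moderate"

    def test_zero_sleep_time_undefined(self):
        with pytest.raises(UndefinedResultError):
            compute_ahi(EventList([]), 0.0)

    @pytest.mark.parametrize("ahi, label", [
        (0.0, "normal"), (4.99, "normal"), (5.0, "mild"), (14.99, "mild"),
        (15.0, "moderate"), (29.99, "moderate"), (30.0, "severe"),
        (80.0, "severe")])
    def test_severity_bins(self, ahi, label):
        assert classify_ahi_severity(ahi) == label

    def test_negative_ahi_rejected(self):
        with pytest.raises(InputError):
            classify_ahi_severity(-0.1)

    def test_summary_merges_overlapping_snores(self):
        events = EventList([
            Event(APNEA, 0.0, 10.0),
            Event("snore", 100.0, 20.0, intensity_db=40.0),
            Event("snore", 110.0, 20.0, intensity_db=42.0),  # overlaps
        ])
        summary = summarize_breathing(events, 3600.0)
        assert summary.snore_duration_min == pytest.approx(0.5)  # 30 s merged
        assert summary.severity == "normal"
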