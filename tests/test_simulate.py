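"""Synthetic-cohort generator: hypnogram chain, vitals, events, devices."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from nightvitals import (
    ConfigurationError,
    EpochSeries,
    SimulationConfig,
    apply_device_model,
    make_cohort,
    simulate_events,
    simulate_hypnogram,
    simulate_reference_vitals,
    wsa_model,
    write_cohort,
)
from nightvitals.epochs import WAKE
from nightvitals.simulate import (
    CHAIN_STATES,
    round_to_quantum,
    true_vitals_series,
)

from conftest import constant_hypnogram, identity_device


class TestHypnogram:
    def test_identity_matrix_stays_wake(self):
        cfg = SimulationConfig(night_duration_s=3600,
                               stage_transition=np.eye(6))
        hyp = simulate_hypnogram(cfg, seed=1)
        assert all(s == WAKE for s in hyp.stages)

    def test_first_epoch_is_wake_and_deterministic(self):
        cfg = SimulationConfig(night_duration_s=7200)
        a = simulate_hypnogram(cfg, seed=42)
        b = simulate_hypnogram(cfg, seed=42)
        assert a.stages[0] == WAKE
        assert np.array_equal(a.stages, b.stages)
        c = simulate_hypnogram(cfg, seed=43)
        assert not np.array_equal(a.stages, c.stages)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.full((6, 6), 0.2)
        with pytest.raises(ConfigurationError):
            SimulationConfig(stage_transition=bad)

    def test_occupancy_matches_stationary_distribution(self):
        """Long-run stage frequencies agree with the chain's stationary
        distribution (independent eigenvector oracle) within 3 SE over
        replicate nights, after discarding a burn-in."""
        cfg = SimulationConfig(night_duration_s=36000)
        P = cfg.stage_transition
        # independent linear-algebra oracle for the stationary vector
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi = pi / pi.sum()

        reps = 120
        burn = 100
        occ = np.zeros((reps, 6))
        for r in range(reps):
            hyp = simulate_hypnogram(cfg, seed=10_000 + r)
            states = np.array([CHAIN_STATES.index(s) for s in hyp.stages[burn:]])
            occ[r] = np.bincount(states, minlength=6) / states.size
        mean = occ.mean(axis=0)
        se = occ.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - pi) <= 3 * np.maximum(se, 1e-4))


class TestReferenceVitals:
    def test_constant_wake_zero_noise_gives_unit_rr(self):
        cfg = SimulationConfig(night_duration_s=3600, hrv_sd=0.0,
                               hr_trend_amplitude=0.0, br_trend_amplitude=0.0,
                               hr_stage_means={**SimulationConfig().hr_stage_means,
                                               WAKE: 60.0},
                               stage_transition=np.eye(6))
        hyp = simulate_hypnogram(cfg, seed=0)
        beats, _, true_hr, _ = simulate_reference_vitals(hyp, cfg, seed=0)
        rr = np.diff(beats)
        assert np.allclose(rr, 1.0, atol=1e-9)
        assert np.allclose(true_hr.values, 60.0)

    def test_respiration_cycle_count_matches_rate(self):
        """Zero-noise respiration at a constant 15 cpm has exactly 15
        cycles per 60-s window, counted by an upward zero-crossing oracle."""
        br_means = {k: 15.0 for k in SimulationConfig().br_stage_means}
        cfg = SimulationConfig(night_duration_s=3600, resp_noise_sd=0.0,
                               br_trend_amplitude=0.0, br_stage_means=br_means,
                               stage_transition=np.eye(6))
        hyp = simulate_hypnogram(cfg, seed=0)
        _, resp, _, true_br = simulate_reference_vitals(hyp, cfg, seed=0)
        assert np.allclose(true_br.values, 15.0)
        x = resp.values
        crossings = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        t = crossings / resp.fs
        for w0 in (0.0, 600.0, 1800.0):
            n_cycles = np.sum((t >= w0) & (t < w0 + 60.0))
            assert n_cycles == 15

    def test_trend_declines_then_upticks(self):
        """Mean heart rate over the first hour exceeds the mean over the
        hour containing the minimum, and the minimum sits in the second
        half of the night."""
        cfg = SimulationConfig(night_duration_s=36000, hr_trend_amplitude=3.0)
        hyp = constant_hypnogram(cfg.n_epochs)
        true_hr, _ = true_vitals_series(hyp, cfg)
        v = true_hr.values
        per_hour = v.reshape(10, -1).mean(axis=1)
        i_min_epoch = np.argmin(v)
        assert i_min_epoch >= v.size // 2
        hour_of_min = i_min_epoch // 120
        assert per_hour[0] > per_hour[hour_of_min]


class TestEvents:
    def test_zero_rates_give_empty_list_and_silent_trace(self):
        cfg = SimulationConfig(night_duration_s=7200, ahi_rate=0.0,
                               snore_propensity=0.0)
        hyp = constant_hypnogram(cfg.n_epochs)
        events, trace = simulate_events(hyp, cfg, seed=0)
        assert len(events) == 0
        assert np.all(trace.values == 0.0)

    def test_poisson_event_rate(self):
        """ahi_rate 20/h over 6 h of sleep: mean respiratory-event count
        over replicates is 120 within 3 SE."""
        cfg = SimulationConfig(night_duration_s=6 * 3600, ahi_rate=20.0,
                               snore_propensity=0.0)
        hyp = constant_hypnogram(cfg.n_epochs)
        counts = [len(simulate_events(hyp, cfg, seed=s)[0].respiratory)
                  for s in range(200)]
        expected = 120.0
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_events_confined_to_sleep_epochs(self):
        cfg = SimulationConfig(night_duration_s=36000, ahi_rate=15.0,
                               snore_propensity=0.2)
        hyp = simulate_hypnogram(cfg, seed=5)
        events, _ = simulate_events(hyp, cfg, seed=5)
        sleep = hyp.is_sleep()
        for ev in events:
            i0 = int(ev.start_s // 30)
            i1 = int((ev.end_s - 1e-9) // 30)
            assert sleep[i0] and sleep[i1]


class TestDeviceModel:
    def setup_method(self):
        self.cfg = SimulationConfig(night_duration_s=3600)
        self.hyp = constant_hypnogram(self.cfg.n_epochs)
        self.true_hr, self.true_br = true_vitals_series(self.hyp, self.cfg)

    def test_identity_model_reproduces_truth(self):
        hr, br, _ = apply_device_model(self.true_hr, self.true_br, self.hyp,
                                       identity_device(), seed=0)
        assert np.allclose(hr.values, self.true_hr.values)
        assert np.allclose(br.values, self.true_br.values)
        assert np.allclose(hr.epoch_start_s, self.true_hr.epoch_start_s)

    def test_rounding_half_away_from_zero(self):
        assert round_to_quantum(np.array([61.4]), 1.0)[0] == 61.0
        assert round_to_quantum(np.array([61.5]), 1.0)[0] == 62.0
        assert round_to_quantum(np.array([-61.5]), 1.0)[0] == -62.0
        grid = self.true_hr.epoch_start_s
        truth = EpochSeries(grid, np.full(len(grid), 61.4), 30.0, unit="bpm")
        hr, _, _ = apply_device_model(truth, None, self.hyp,
                                      identity_device(rounding_quantum=1.0), seed=0)
        assert np.all(hr.values == 61.0)

    def test_clipping_to_device_range(self):
        grid = self.true_hr.epoch_start_s
        truth = EpochSeries(grid, np.full(len(grid), 100.0), 30.0, unit="bpm")
        model = identity_device(hr_clip=(40.0, 90.0))
        hr, _, _ = apply_device_model(truth, None, self.hyp, model, seed=0)
        assert np.all(hr.values == 90.0)

    def test_missingness_removes_values_not_timestamps(self):
        hyp = constant_hypnogram(len(self.hyp), stage="W")
        model = identity_device(wake_missing_prob=0.5)
        hr, _, _ = apply_device_model(self.true_hr, self.true_br, hyp, model, seed=1)
        assert len(hr) == len(self.true_hr)          # grid conserved
        assert np.isnan(hr.values).any()

    def test_clock_lag_shifts_timestamps(self):
        model = identity_device(clock_lag_s=90.0)
        hr, _, dev_hyp = apply_device_model(self.true_hr, self.true_br,
                                            self.hyp, model, seed=0)
        assert np.allclose(hr.epoch_start_s, self.true_hr.epoch_start_s + 90.0)
        assert np.allclose(dev_hyp.epoch_start_s, self.hyp.epoch_start_s + 90.0)

    def test_substep_averaging_reduces_noise(self):
        """4-s substep HR averaged to 30 s has per-epoch noise SD close to
        noise_sd / sqrt(m) for m substeps."""
        grid = self.true_hr.epoch_start_s
        truth = EpochSeries(grid, np.full(len(grid), 60.0), 30.0, unit="bpm")
        model = identity_device(hr_substep_s=4.0, noise_sd_hr=8.0)
        sds = []
        for s in range(30):
            hr, _, _ = apply_device_model(truth, None, self.hyp, model, seed=s)
            sds.append(np.std(hr.values - 60.0, ddof=1))
        m = round(30 / 4)
        assert np.mean(sds) == pytest.approx(8.0 / np.sqrt(m), rel=0.1)

    def test_epoch_count_conserves_night_duration(self, small_cohort):
        for record in small_cohort:
            night = record.lights_on_s - record.lights_off_s
            for dev in record.devices.values():
                for series in (dev.hr, dev.br):
                    if series is not None:
                        assert len(series) * series.epoch_s == pytest.approx(night)


class TestCohort:
    def test_single_participant_has_all_devices(self, small_config):
        cohort = make_cohort(
            SimulationConfig(n_participants=1, night_duration_s=3600),
            [wsa_model(), identity_device()], seed=0)
        assert len(cohort) == 1
        assert set(cohort[0].devices) == {"wsa", "ideal"}

    def test_same_seed_serializes_identically(self, tmp_path):
        cfg = SimulationConfig(n_participants=2, night_duration_s=3600)
        digests = []
        for run in ("a", "b"):
            cohort = make_cohort(cfg, [wsa_model()], seed=11)
            out = tmp_path / run
            write_cohort(cohort, out, seed=11)
            h = hashlib.sha256()
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    h.update(p.relative_to(out).as_posix().encode())
                    h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_device_insertion_leaves_other_channels_unchanged(self):
        cfg = SimulationConfig(n_participants=1, night_duration_s=3600)
        one = make_cohort(cfg, [wsa_model()], seed=5)[0]
        two = make_cohort(cfg, [wsa_model(), identity_device()], seed=5)[0]
        assert np.array_equal(one.beats_s, two.beats_s)
        assert np.array_equal(one.devices["wsa"].br.values,
                              two.devices["wsa"].br.values,
                              equal_nan=True)

    def test_cohort_mean_heart_rate_matches_population(self):
        """The default cohort reproduces the population mean overnight
        heart rate of 62.2 bpm (between-participant SD 8.9) within 3 SE
        at n = 35."""
        cfg = SimulationConfig(n_participants=35)
        cohort = make_cohort(cfg, [], seed=2)
        nightly = []
        for record in cohort:
            nightly.append(np.nanmean(record.ref_hr.values)
                           if record.ref_hr is not None else
                           60.0 / np.mean(np.diff(record.beats_s)))
        tol = 3 * 8.9 / np.sqrt(35)
        assert abs(np.mean(nightly) - 62.2) <= tol
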