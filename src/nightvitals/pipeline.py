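"""End-to-end evaluation of contactless devices against the reference.

For a cohort of :class:`~nightvitals.records.NightRecord` objects this
module runs the standard validation analyses: all-night (nightly-mean)
agreement summaries, vigilance-stage-stratified agreement, the effect of
temporal resolution (1 / 10 / 60-minute window averages with
absolute-error quantiles), overnight time courses of mean-centered
vitals, snore concordance, and AHI/BDI concordance.

The orchestration object is :class:`DeviceEvaluation`: construct it from
a cohort and a device name, call :meth:`~DeviceEvaluation.fit`, and read
the per-analysis results off the returned
:class:`DeviceEvaluationResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agreement import (
    AgreementReport,
    AgreementResults,
    ConfusionMatrix2x2,
    PairedAgreement,
    RegressionResult,
    abs_error_quantiles,
    mcc,
    r_squared,
)
from .epochs import (
    EXCLUDED_STAGES,
    EpochSeries,
    Hypnogram,
    N1,
    N2,
    N3,
    REM,
    WAKE,
)
from .errors import InputError, InsufficientDataError
from .harmonize import (
    PairedEpochs,
    align_by_crosscorr,
    build_pairs,
    resample_hypnogram,
    resample_to_grid,
    window_average,
)
from .records import NightRecord
from .reference import (
    br_from_respiration,
    classify_ahi_severity,
    compute_ahi,
    hr_from_beats,
    score_snore,
)

STRATIFICATION_STAGES = (WAKE, N1, N2, N3, REM)
#: Minimum pairs for a stage stratum to be reported.
MIN_STAGE_PAIRS = 10
#: Window lengths for the temporal-resolution analysis, seconds.
RESOLUTION_WINDOWS_S = (60.0, 600.0, 3600.0)


@dataclass(frozen=True)
class AcceptanceThresholds:
    """Permissible error levels for a clinically acceptable monitor:
    heart rate within 10% MAPE or ±5 bpm bias; breathing rate within
    ±4 cpm bias. Bounds are inclusive."""

    hr_mape_limit_pct: float = 10.0
    hr_bias_limit_bpm: float = 5.0
    br_bias_limit_cpm: float = 4.0


def acceptability_check(report: AgreementReport,
                        thresholds: AcceptanceThresholds = AcceptanceThresholds()
                        ) -> bool:
    """Pass/fail against the acceptability thresholds.

    Heart rate passes when MAPE <= 10% *or* |bias| <= 5 bpm; breathing
    rate passes when |bias| <= 4 cpm (inclusive bounds).
    """
    if report.variable == "hr":
        return (report.mape_pct <= thresholds.hr_mape_limit_pct
                or abs(report.bias) <= thresholds.hr_bias_limit_bpm)
    return abs(report.bias) <= thresholds.br_bias_limit_cpm


def reference_epoch_series(record: NightRecord, variable: str) -> EpochSeries:
    """Reference per-epoch vitals extracted from the raw channels."""
    hyp = record.hypnogram
    if hyp is None:
        raise InputError(f"{record.participant_id}: no reference hypnogram")
    n = len(hyp)
    start = float(hyp.epoch_start_s[0])
    if variable == "hr" and record.ref_hr is not None:
        return record.ref_hr
    if variable == "br" and record.ref_br is not None:
        return record.ref_br
    if variable == "hr":
        if record.beats_s is None:
            raise InputError(f"{record.participant_id}: no beat timestamps")
        return hr_from_beats(record.beats_s, start, n, hyp.epoch_s)
    if variable == "br":
        if record.respiration is None:
            raise InputError(f"{record.participant_id}: no respiration waveform")
        return br_from_respiration(record.respiration, start, n, hyp.epoch_s)
    raise InputError("variable must be 'hr' or 'br'")


def harmonize_night(record: NightRecord, device_name: str, variable: str,
                    max_lag_s: float = 300.0, align: bool = True
                    ) -> Tuple[PairedEpochs, float]:
    """Resample, synchronize and pair one night's device channel.

    Returns the valid epoch pairs on the 30-s reference grid and the
    estimated device clock lag (0 when ``align`` is off).
    """
    dev = record.device(device_name)
    series = dev.hr if variable == "hr" else dev.br
    if series is None:
        raise InputError(f"device {device_name!r} does not report {variable!r}")
    ref = reference_epoch_series(record, variable)
    ref_hyp = record.hypnogram
    dev30 = resample_to_grid(series, ref_hyp.epoch_s)
    lag = 0.0
    if align:
        lag = align_by_crosscorr(dev30, dev.hypnogram, ref, ref_hyp,
                                 max_lag_s=max_lag_s, step_s=ref_hyp.epoch_s)
    shifted = dev30.shift(-lag)
    dev_hyp = dev.hypnogram.shift(-lag) if dev.hypnogram is not None else None
    pairs = build_pairs(shifted, ref, ref_hyp, dev_hyp,
                        participant_id=record.participant_id, variable=variable)
    return pairs, lag


def _nightly_pairs(cohort: Sequence[NightRecord], device: str, variable: str,
                   max_lag_s: float = 300.0, align: bool = True
                   ) -> Dict[str, PairedEpochs]:
    out = {}
    for record in cohort:
        try:
            pairs, _ = harmonize_night(record, device, variable,
                                       max_lag_s=max_lag_s, align=align)
        except InputError:
            continue
        if len(pairs):
            out[record.participant_id] = pairs
    return out


def _pooled_model(pairs_by_night: Dict[str, PairedEpochs], variable: str,
                  label: str = "") -> PairedAgreement:
    dev = np.concatenate([p.device_values for p in pairs_by_night.values()])
    ref = np.concatenate([p.reference_values for p in pairs_by_night.values()])
    ids = np.concatenate([np.repeat(pid, len(p))
                          for pid, p in pairs_by_night.items()])
    stages = np.concatenate([p.stage_labels for p in pairs_by_night.values()])
    return PairedAgreement(dev, ref, participant_ids=ids, stage_labels=stages,
                           variable=variable, label=label)


def all_night_summary(cohort: Sequence[NightRecord], device: str, variable: str,
                      exclude_ids: Optional[Sequence[str]] = None,
                      max_lag_s: float = 300.0) -> AgreementResults:
    """All-night agreement: one nightly mean per participant-night.

    Nightly means are taken over valid pairs only; the agreement suite is
    then computed across nights. ``exclude_ids`` removes listed
    participants (the explicit outlier policy — e.g. a night dominated by
    arrhythmia — never an automatic rule).
    """
    exclude = set(exclude_ids or ())
    nightly = _nightly_pairs(cohort, device, variable, max_lag_s=max_lag_s)
    ids = [pid for pid in nightly if pid not in exclude]
    if len(ids) < 3:
        raise InsufficientDataError("all-night summary needs >= 3 nights with pairs")
    dev_means = np.array([nightly[i].device_values.mean() for i in ids])
    ref_means = np.array([nightly[i].reference_values.mean() for i in ids])
    model = PairedAgreement(dev_means, ref_means, participant_ids=ids,
                            variable=variable, label=f"{device} all-night")
    return model.fit(aggregate="pooled")


def stage_stratified(cohort: Sequence[NightRecord], device: str, variable: str,
                     max_lag_s: float = 300.0
                     ) -> Dict[str, Optional[AgreementResults]]:
    """Agreement within each reference vigilance stage.

    Strata with fewer than ``MIN_STAGE_PAIRS`` pooled pairs are reported
    as ``None`` rather than raising.
    """
    nightly = _nightly_pairs(cohort, device, variable, max_lag_s=max_lag_s)
    if not nightly:
        raise InsufficientDataError("no valid pairs in cohort")
    model = _pooled_model(nightly, variable)
    out: Dict[str, Optional[AgreementResults]] = {}
    for stage in STRATIFICATION_STAGES:
        mask = model.stage_labels == stage
        if mask.sum() < MIN_STAGE_PAIRS:
            out[stage] = None
            continue
        sub = PairedAgreement(model.device[mask], model.reference[mask],
                              participant_ids=model.participant_ids[mask],
                              variable=variable, label=f"{device} {stage}")
        out[stage] = sub.fit(aggregate="pooled")
    return out


@dataclass
class ResolutionResult:
    window_s: float
    results: AgreementResults
    quantiles: Dict[float, float]


def multiresolution_analysis(cohort: Sequence[NightRecord], device: str,
                             variable: str,
                             windows_s: Sequence[float] = RESOLUTION_WINDOWS_S,
                             max_lag_s: float = 300.0
                             ) -> Dict[float, ResolutionResult]:
    """Agreement at coarser temporal resolutions.

    Pairs are averaged over non-overlapping windows anchored at
    lights-off, pooled across nights, and the full metric suite plus
    median/90th-percentile absolute errors computed per resolution.
    """
    nightly = _nightly_pairs(cohort, device, variable, max_lag_s=max_lag_s)
    if not nightly:
        raise InsufficientDataError("no valid pairs in cohort")
    anchors = {r.participant_id: r.lights_off_s for r in cohort}
    out: Dict[float, ResolutionResult] = {}
    for w in windows_s:
        windowed = {pid: window_average(p, w, anchor_s=anchors.get(pid, 0.0))
                    for pid, p in nightly.items()}
        model = _pooled_model(windowed, variable,
                              label=f"{device} {int(w / 60)}-min")
        res = model.fit(aggregate="pooled")
        qs, _, _ = abs_error_quantiles(model.device, model.reference)
        out[w] = ResolutionResult(window_s=w, results=res, quantiles=qs)
    return out


@dataclass
class TimeCourseResult:
    table: pd.DataFrame        # hour, device_mean, device_sd, ref_mean, ref_sd, n
    trend_mape_pct: float


def time_course_analysis(cohort: Sequence[NightRecord], device: str,
                         variable: str, bin_s: float = 3600.0,
                         eps: float = 0.05, max_lag_s: float = 300.0
                         ) -> TimeCourseResult:
    """Overnight time course of mean-centered vitals during sleep.

    Per night, paired vitals are restricted to sleep epochs, mean-centered
    within the night, and averaged per hourly bin from lights-off. The
    cohort mean ± SD per bin describes the trajectory; trend similarity is
    the MAPE between the device and reference cohort-mean hourly series,
    excluding bins where the mean-centered reference is within ``eps`` of
    zero (raw percentage errors blow up at sign changes of the centered
    trend).
    """
    nightly = _nightly_pairs(cohort, device, variable, max_lag_s=max_lag_s)
    anchors = {r.participant_id: r.lights_off_s for r in cohort}
    rows = []
    sleep_stages = {N1, N2, N3, REM}
    for pid, pairs in nightly.items():
        sleep = np.isin(pairs.stage_labels, list(sleep_stages))
        if sleep.sum() < 2:
            continue
        sub = pairs.subset(sleep)
        d_c = sub.device_values - sub.device_values.mean()
        r_c = sub.reference_values - sub.reference_values.mean()
        hours = np.floor((sub.epoch_start_s - anchors.get(pid, 0.0)) / bin_s).astype(int)
        for h in np.unique(hours):
            m = hours == h
            rows.append({"participant_id": pid, "hour": int(h),
                         "device": d_c[m].mean(), "reference": r_c[m].mean()})
    if not rows:
        raise InsufficientDataError("no sleep pairs for the time-course analysis")
    df = pd.DataFrame(rows)
    table = df.groupby("hour").agg(
        device_mean=("device", "mean"), device_sd=("device", "std"),
        ref_mean=("reference", "mean"), ref_sd=("reference", "std"),
        n=("device", "size")).reset_index()
    if len(table) < 2:
        raise InsufficientDataError("fewer than 2 usable hourly bins")
    usable = np.abs(table["ref_mean"]) >= eps
    if usable.sum() == 0:
        trend_mape = float("nan")
    else:
        t = table[usable]
        trend_mape = float(np.mean(np.abs(t["device_mean"] - t["ref_mean"])
                                   / np.abs(t["ref_mean"])) * 100.0)
    return TimeCourseResult(table=table, trend_mape_pct=trend_mape)


@dataclass
class SnoreAnalysisResult:
    per_night: pd.DataFrame          # ref/device snore minutes, snorer flags
    duration_regression: RegressionResult
    confusion: ConfusionMatrix2x2
    mcc: float
    stage_table: pd.DataFrame        # reference-stage distribution of device snore
    intensity_detected_db: float
    intensity_undetected_db: float


def snore_analysis(cohort: Sequence[NightRecord], device: str = "wsa",
                   amplitude_threshold_db: float = 30.0,
                   min_duration_s: float = 0.3) -> Optional[SnoreAnalysisResult]:
    """Concordance of device snore detection with the scored reference.

    Per night: reference snore events are scored from the intensity trace
    (30 dB threshold, 300 ms minimum duration) and compared to the device
    per-epoch snore flags — total minutes (regression), participant-level
    snorer classification (2x2 confusion, MCC), the reference-stage
    distribution of device-flagged epochs, and the reference intensity of
    detected versus undetected snore epochs.
    """
    rows = []
    stage_counts: Dict[str, int] = {}
    det_int: List[float] = []
    undet_int: List[float] = []
    for record in cohort:
        dev = record.devices.get(device)
        if (record.snore_trace is None or dev is None
                or dev.snore_epochs is None or record.hypnogram is None):
            continue
        hyp = record.hypnogram
        n = len(hyp)
        events, ref_binary = score_snore(record.snore_trace,
                                         amplitude_threshold_db,
                                         min_duration_s,
                                         epoch_s=hyp.epoch_s, n_epochs=n)
        dev_binary = dev.snore_epochs.values[:n]
        if dev_binary.size < n:
            dev_binary = np.pad(dev_binary, (0, n - dev_binary.size))
        ref_min = events.total_duration_s() / 60.0
        dev_min = float(dev_binary.sum()) * hyp.epoch_s / 60.0
        rows.append({"participant_id": record.participant_id,
                     "ref_snore_min": ref_min, "device_snore_min": dev_min,
                     "ref_snorer": ref_min > 0, "device_snorer": bool(dev_binary.any())})
        for stage in hyp.stages[dev_binary.astype(bool)]:
            stage_counts[stage] = stage_counts.get(stage, 0) + 1
        # reference intensity per reference-snore epoch, split by detection
        ep_int = np.zeros(n)
        for ev in events:
            first = int(np.floor((ev.start_s - hyp.epoch_start_s[0]) / hyp.epoch_s))
            last = int(np.floor((ev.end_s - 1e-9 - hyp.epoch_start_s[0]) / hyp.epoch_s))
            for i in range(max(0, first), min(n - 1, last) + 1):
                ep_int[i] = max(ep_int[i], ev.intensity_db)
        for i in np.flatnonzero(ref_binary[:n]):
            (det_int if dev_binary[i] else undet_int).append(ep_int[i])
    if not rows:
        warnings.warn(f"no nights with snore channels for device {device!r};"
                      " snore analysis skipped")
        return None
    df = pd.DataFrame(rows)
    tp = int((df.ref_snorer & df.device_snorer).sum())
    fn = int((df.ref_snorer & ~df.device_snorer).sum())
    fp = int((~df.ref_snorer & df.device_snorer).sum())
    tn = int((~df.ref_snorer & ~df.device_snorer).sum())
    cm = ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)
    try:
        reg = r_squared(df.ref_snore_min.to_numpy(), df.device_snore_min.to_numpy())
    except (InputError, InsufficientDataError):
        reg = RegressionResult(float("nan"), float("nan"), float("nan"))
    stage_table = (pd.Series(stage_counts, dtype=float)
                   .rename("device_snore_epochs").to_frame())
    return SnoreAnalysisResult(
        per_night=df, duration_regression=reg, confusion=cm, mcc=mcc(cm),
        stage_table=stage_table,
        intensity_detected_db=float(np.mean(det_int)) if det_int else float("nan"),
        intensity_undetected_db=float(np.mean(undet_int)) if undet_int else float("nan"),
    )


@dataclass
class AhiAnalysisResult:
    per_night: pd.DataFrame
    regression: RegressionResult
    mae: float
    severity_confusion: pd.DataFrame
    used_bdi_proxy: bool


def ahi_analysis(cohort: Sequence[NightRecord], device: str = "wsa"
                 ) -> Optional[AhiAnalysisResult]:
    """Device AHI against reference AHI.

    When the device reports only the breathing disorder index (BDI), half
    the BDI serves as the device AHI (the BDI tracks twice the AHI).
    Reports the regression of device on reference AHI, the MAE, and the
    severity-class cross-tabulation.
    """
    rows = []
    used_proxy = False
    for record in cohort:
        dev = record.devices.get(device)
        if dev is None:
            continue
        if dev.ahi is not None:
            dev_ahi = dev.ahi
        elif dev.bdi is not None:
            dev_ahi = dev.bdi / 2.0
            used_proxy = True
        else:
            continue
        ref_ahi = record.metadata.get("ahi_reference")
        if ref_ahi is None and record.events is not None and record.hypnogram is not None:
            tst = record.hypnogram.total_sleep_time_s()
            if tst <= 0:
                continue
            ref_ahi = compute_ahi(record.events, tst)
        if ref_ahi is None:
            continue
        rows.append({"participant_id": record.participant_id,
                     "ref_ahi": float(ref_ahi), "device_ahi": float(dev_ahi),
                     "ref_severity": classify_ahi_severity(float(ref_ahi)),
                     "device_severity": classify_ahi_severity(float(dev_ahi))})
    if not rows:
        warnings.warn(f"no nights with breathing-disturbance estimates for"
                      f" device {device!r}; AHI analysis skipped")
        return None
    df = pd.DataFrame(rows)
    try:
        reg = r_squared(df.ref_ahi.to_numpy(), df.device_ahi.to_numpy())
    except (InputError, InsufficientDataError):
        reg = RegressionResult(float("nan"), float("nan"), float("nan"))
    mae = float(np.mean(np.abs(df.device_ahi - df.ref_ahi)))
    confusion = pd.crosstab(df.ref_severity, df.device_severity)
    return AhiAnalysisResult(per_night=df, regression=reg, mae=mae,
                             severity_confusion=confusion,
                             used_bdi_proxy=used_proxy)


# ---------------------------------------------------------------------------
# Orchestration model
# ---------------------------------------------------------------------------

class DeviceEvaluation:
    """Full evaluation of one device against the cohort reference.

    Parameters
    ----------
    cohort : sequence of NightRecord
    device : str
        Device name present in the records.
    variables : sequence of {"hr", "br"}, optional
        Defaults to whatever the device reports.
    """

    def __init__(self, cohort: Sequence[NightRecord], device: str,
                 variables: Optional[Sequence[str]] = None,
                 max_lag_s: float = 300.0,
                 thresholds: AcceptanceThresholds = AcceptanceThresholds(),
                 exclude_ids: Optional[Sequence[str]] = None):
        self.cohort = list(cohort)
        self.device = device
        if variables is None:
            variables = []
            for record in self.cohort:
                dev = record.devices.get(device)
                if dev is not None:
                    if dev.hr is not None:
                        variables.append("hr")
                    if dev.br is not None:
                        variables.append("br")
                    break
        self.variables = list(dict.fromkeys(variables))
        self.max_lag_s = max_lag_s
        self.thresholds = thresholds
        self.exclude_ids = list(exclude_ids or ())

    def fit(self, resolutions: bool = True, time_course: bool = True,
            snore: bool = True, ahi: bool = True) -> "DeviceEvaluationResults":
        all_night: Dict[str, AgreementResults] = {}
        stages: Dict[str, Dict[str, Optional[AgreementResults]]] = {}
        multires: Dict[str, Dict[float, ResolutionResult]] = {}
        courses: Dict[str, TimeCourseResult] = {}
        acceptable: Dict[str, bool] = {}
        for var in self.variables:
            res = all_night_summary(self.cohort, self.device, var,
                                    exclude_ids=self.exclude_ids,
                                    max_lag_s=self.max_lag_s)
            all_night[var] = res
            acceptable[var] = acceptability_check(res.report, self.thresholds)
            stages[var] = stage_stratified(self.cohort, self.device, var,
                                           max_lag_s=self.max_lag_s)
            if resolutions:
                multires[var] = multiresolution_analysis(
                    self.cohort, self.device, var, max_lag_s=self.max_lag_s)
            if time_course:
                try:
                    courses[var] = time_course_analysis(
                        self.cohort, self.device, var, max_lag_s=self.max_lag_s)
                except InsufficientDataError:
                    pass
        snore_res = snore_analysis(self.cohort, self.device) if snore else None
        ahi_res = ahi_analysis(self.cohort, self.device) if ahi else None
        return DeviceEvaluationResults(self, all_night, stages, multires,
                                       courses, snore_res, ahi_res, acceptable)


class DeviceEvaluationResults:
    """Results bundle for one device: per-variable agreement at every level."""

    def __init__(self, model: DeviceEvaluation,
                 all_night: Dict[str, AgreementResults],
                 stages: Dict[str, Dict[str, Optional[AgreementResults]]],
                 multiresolution: Dict[str, Dict[float, ResolutionResult]],
                 time_courses: Dict[str, TimeCourseResult],
                 snore: Optional[SnoreAnalysisResult],
                 ahi: Optional[AhiAnalysisResult],
                 acceptable: Dict[str, bool]):
        self.model = model
        self.all_night = all_night
        self.stages = stages
        self.multiresolution = multiresolution
        self.time_courses = time_courses
        self.snore = snore
        self.ahi = ahi
        self.acceptable = acceptable

    def summary(self) -> str:
        parts = [f"Device evaluation: {self.model.device}"]
        for var, res in self.all_night.items():
            parts.append("")
            parts.append(res.summary())
            verdict = "PASS" if self.acceptable.get(var) else "FAIL"
            parts.append(f"acceptability ({var})  {verdict}")
        if self.snore is not None:
            parts.append("")
            parts.append(f"snore: r2={self.snore.duration_regression.r2:.2f}, "
                         f"MCC={self.snore.mcc:.2f}")
        if self.ahi is not None:
            parts.append(f"AHI:   r2={self.ahi.regression.r2:.2f}, "
                         f"MAE={self.ahi.mae:.2f} events/h"
                         + (" (BDI/2 proxy)" if self.ahi.used_bdi_proxy else ""))
        return "\n".join(parts)
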