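"""Grid harmonization, clock synchronization, and epoch pairing.

Device series arrive on their own grids (60-s epochs for the WSA-style
device, 30-s for the others) with an unknown clock offset relative to the
polysomnograph. This module puts everything on a common 30-s grid,
estimates the device clock lag by maximizing an equal-weight sum of the
vitals cross-correlation and the hypnogram epoch-agreement fraction over
lags within ±5 minutes, and builds complete epoch pairs, excluding epochs
scored artifact or no-presence on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .epochs import (
    EXCLUDED_STAGES,
    EpochSeries,
    Hypnogram,
    REFERENCE_STAGES,
)
from .errors import AlignmentError, InputError

#: Maximum clock lag searched, seconds (a 5-minute window either way).
MAX_LAG_S = 300.0


@dataclass
class PairedEpochs:
    """Complete device/reference epoch pairs with their stage context."""

    epoch_start_s: np.ndarray
    device_values: np.ndarray
    reference_values: np.ndarray
    stage_labels: np.ndarray
    participant_id: str
    variable: str
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.device_values = np.asarray(self.device_values, dtype=float)
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        self.stage_labels = np.asarray(self.stage_labels, dtype=object)
        n = self.device_values.size
        if not (self.reference_values.size == n == self.stage_labels.size
                == self.epoch_start_s.size):
            raise InputError("paired vectors must have equal length")
        if np.any(np.isnan(self.device_values)) or np.any(np.isnan(self.reference_values)):
            raise InputError("pairs must be complete (no missing values)")
        if self.variable not in ("hr", "br"):
            raise InputError("variable must be 'hr' or 'br'")

    def __len__(self) -> int:
        return self.device_values.size

    @property
    def differences(self) -> np.ndarray:
        """Device minus reference, per pair."""
        return self.device_values - self.reference_values

    def subset(self, mask: np.ndarray) -> "PairedEpochs":
        return PairedEpochs(self.epoch_start_s[mask], self.device_values[mask],
                            self.reference_values[mask], self.stage_labels[mask],
                            self.participant_id, self.variable, self.epoch_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_start_s": self.epoch_start_s,
            "device": self.device_values,
            "reference": self.reference_values,
            "stage": self.stage_labels,
            "participant_id": self.participant_id,
        })


def concat_pairs(pairs_list: Sequence[PairedEpochs]) -> pd.DataFrame:
    """Pool pairs across nights into one long DataFrame."""
    if not pairs_list:
        raise InputError("no pairs to concatenate")
    frames = [p.to_frame() for p in pairs_list]
    return pd.concat(frames, ignore_index=True)


def resample_to_grid(series: EpochSeries, target_epoch_s: float = 30.0) -> EpochSeries:
    """Re-grid a series to ``target_epoch_s`` epochs.

    Coarser-to-finer conversion duplicates each value across its
    sub-epochs (upsampling); finer-to-coarser takes the mean of the
    available sub-epoch values, missing only when all sub-values are
    missing. Epoch lengths must be integer multiples of one another.
    """
    if abs(series.epoch_s - target_epoch_s) < 1e-9:
        return EpochSeries(series.epoch_start_s.copy(), series.values.copy(),
                           series.epoch_s, unit=series.unit)
    if series.epoch_s > target_epoch_s:
        ratio = series.epoch_s / target_epoch_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise InputError("incommensurate epoch lengths")
        f = int(round(ratio))
        values = np.repeat(series.values, f)
        grid = (series.epoch_start_s[0]
                + target_epoch_s * np.arange(values.size, dtype=float))
        return EpochSeries(grid, values, target_epoch_s, unit=series.unit)
    ratio = target_epoch_s / series.epoch_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise InputError("incommensurate epoch lengths")
    f = int(round(ratio))
    n_out = series.values.size // f
    if n_out == 0:
        raise InputError("series shorter than one target epoch")
    block = series.values[: n_out * f].reshape(n_out, f)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(block, axis=1)
    grid = series.epoch_start_s[0] + target_epoch_s * np.arange(n_out, dtype=float)
    return EpochSeries(grid, values, target_epoch_s, unit=series.unit)


def resample_hypnogram(hypnogram: Hypnogram, target_epoch_s: float = 30.0) -> Hypnogram:
    """Re-grid a hypnogram: coarser-to-finer duplicates labels;
    finer-to-coarser keeps the first sub-epoch label."""
    if abs(hypnogram.epoch_s - target_epoch_s) < 1e-9:
        return hypnogram
    if hypnogram.epoch_s > target_epoch_s:
        f = int(round(hypnogram.epoch_s / target_epoch_s))
        stages = np.repeat(hypnogram.stages, f)
        grid = (hypnogram.epoch_start_s[0]
                + target_epoch_s * np.arange(stages.size, dtype=float))
        return Hypnogram(grid, stages, target_epoch_s, vocabulary=hypnogram.vocabulary)
    f = int(round(target_epoch_s / hypnogram.epoch_s))
    stages = hypnogram.stages[::f]
    grid = (hypnogram.epoch_start_s[0]
            + target_epoch_s * np.arange(stages.size, dtype=float))
    return Hypnogram(grid, stages, target_epoch_s, vocabulary=hypnogram.vocabulary)


def _overlap_values(a_grid: np.ndarray, a_vals: np.ndarray,
                    b_grid: np.ndarray, b_vals: np.ndarray,
                    epoch_s: float) -> Tuple[np.ndarray, np.ndarray]:
    """Values of a and b on their common epoch grid (by integer epoch key)."""
    ka = np.round(a_grid / epoch_s).astype(np.int64)
    kb = np.round(b_grid / epoch_s).astype(np.int64)
    common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    return a_vals[ia], b_vals[ib]


def _ncc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mean-centered overlapping values; 0 when
    degenerate (too few pairs or zero variance) so constant vitals leave
    the decision to the hypnogram term and the tie-break."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        return 0.0
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def align_by_crosscorr(device_vitals: Optional[EpochSeries],
                       device_hypnogram: Optional[Hypnogram],
                       ref_vitals: Optional[EpochSeries],
                       ref_hypnogram: Optional[Hypnogram],
                       max_lag_s: float = MAX_LAG_S,
                       step_s: float = 30.0) -> float:
    """Estimate the device clock lag against the reference.

    Searches lags in multiples of ``step_s`` over ``[-max_lag_s, +max_lag_s]``
    and returns the lag maximizing the equal-weight sum of (a) the
    normalized cross-correlation of the mean-centered vitals and (b) the
    hypnogram epoch-agreement fraction (device and reference staging mapped
    to the common 4-state vocabulary). A device whose clock runs ``lag``
    seconds ahead of the reference is matched by comparing its value at
    ``t + lag`` with the reference at ``t``; shifting the device series by
    ``-lag`` therefore aligns it. Ties break toward the smallest ``|lag|``,
    then toward the negative lag.
    """
    if device_vitals is None and device_hypnogram is None:
        raise AlignmentError("nothing to align: no device channels")
    ref_hyp4 = (ref_hypnogram.to_device_vocabulary()
                if ref_hypnogram is not None
                and ref_hypnogram.vocabulary == REFERENCE_STAGES
                else ref_hypnogram)

    n_steps = int(round(max_lag_s / step_s))
    lags = [k * step_s for k in range(-n_steps, n_steps + 1)]
    lags.sort(key=lambda L: (abs(L), L))  # tie-break order: small |lag|, then negative

    best_lag, best_score = None, -np.inf
    any_overlap = False
    for lag in lags:
        score = 0.0
        n_terms = 0
        if device_vitals is not None and ref_vitals is not None:
            dv, rv = _overlap_values(device_vitals.epoch_start_s - lag,
                                     device_vitals.values,
                                     ref_vitals.epoch_start_s, ref_vitals.values,
                                     step_s)
            if dv.size:
                any_overlap = True
            score += _ncc(dv, rv)
            n_terms += 1
        if device_hypnogram is not None and ref_hyp4 is not None:
            dh = resample_hypnogram(device_hypnogram, step_s)
            ds, rs = _overlap_values(dh.epoch_start_s - lag,
                                     dh.stages,
                                     ref_hyp4.epoch_start_s, ref_hyp4.stages,
                                     step_s)
            if ds.size:
                any_overlap = True
                score += float(np.mean(ds == rs))
            n_terms += 1
        if n_terms and score > best_score + 1e-12:
            best_score, best_lag = score, lag
    if not any_overlap or best_lag is None:
        raise AlignmentError("no overlapping support between device and reference")
    return float(best_lag)


def build_pairs(device: EpochSeries, reference: EpochSeries,
                ref_hypnogram: Hypnogram, device_hypnogram: Optional[Hypnogram],
                participant_id: str = "", variable: str = "hr") -> PairedEpochs:
    """Valid epoch pairs on the common 30-s grid.

    Keeps epochs where both values are present and neither hypnogram is
    scored artifact or no-presence; carries the reference stage labels.
    """
    for s in (device, reference):
        if abs(s.epoch_s - ref_hypnogram.epoch_s) > 1e-9:
            raise InputError("device, reference and hypnogram must share one grid")
    epoch_s = reference.epoch_s
    ka = np.round(device.epoch_start_s / epoch_s).astype(np.int64)
    kb = np.round(reference.epoch_start_s / epoch_s).astype(np.int64)
    kh = np.round(ref_hypnogram.epoch_start_s / epoch_s).astype(np.int64)
    common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    common2, ic, ih = np.intersect1d(common, kh, return_indices=True)
    ia, ib = ia[ic], ib[ic]

    dvals = device.values[ia]
    rvals = reference.values[ib]
    stages = ref_hypnogram.stages[ih]
    keep = (~np.isnan(dvals) & ~np.isnan(rvals)
            & ~np.isin(stages, list(EXCLUDED_STAGES)))
    if device_hypnogram is not None:
        dh = resample_hypnogram(device_hypnogram, epoch_s)
        kd = np.round(dh.epoch_start_s / epoch_s).astype(np.int64)
        key_to_stage = dict(zip(kd.tolist(), dh.stages.tolist()))
        dstages = np.array([key_to_stage.get(k) for k in common2], dtype=object)
        keep &= ~np.isin(dstages, list(EXCLUDED_STAGES)) & (dstages != None)  # noqa: E711
    return PairedEpochs(common2[keep] * epoch_s, dvals[keep], rvals[keep],
                        stages[keep], participant_id, variable, epoch_s)


def window_average(pairs: PairedEpochs, window_s: float,
                   anchor_s: Optional[float] = None) -> PairedEpochs:
    """Average pairs over non-overlapping windows anchored at lights-off.

    Both sides are averaged over the *same* epoch set inside each window,
    so missingness cannot bias one side; windows containing no pairs are
    dropped. The window's stage label is the modal reference stage of its
    contributing epochs.
    """
    if window_s % pairs.epoch_s != 0:
        raise InputError("window_s must be a multiple of the pair epoch length")
    if anchor_s is None:
        anchor_s = float(pairs.epoch_start_s.min()) if len(pairs) else 0.0
    idx = np.floor((pairs.epoch_start_s - anchor_s) / window_s).astype(int)
    out_t, out_d, out_r, out_s = [], [], [], []
    for w in np.unique(idx):
        m = idx == w
        out_t.append(anchor_s + w * window_s)
        out_d.append(pairs.device_values[m].mean())
        out_r.append(pairs.reference_values[m].mean())
        labels, counts = np.unique(pairs.stage_labels[m], return_counts=True)
        out_s.append(labels[np.argmax(counts)])
    return PairedEpochs(np.array(out_t), np.array(out_d), np.array(out_r),
                        np.array(out_s, dtype=object), pairs.participant_id,
                        pairs.variable, window_s)
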