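"""Epoch-gridded containers: numeric vital-sign series and hypnograms.

Everything downstream of raw signal extraction works on a uniform epoch grid
(30 s for polysomnography scoring, 60 s for some devices). ``EpochSeries``
holds one numeric value per epoch (heart rate in bpm or breathing rate in
cpm) with NaN encoding missing epochs; ``Hypnogram`` holds one categorical
vigilance label per epoch.

Grids are addressed by the left edge of each half-open epoch interval
``[start, start + epoch_s)``, in seconds from the start of the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError

#: Reference (PSG) vigilance states.
WAKE = "W"
N1 = "N1"
N2 = "N2"
N3 = "N3"
REM = "REM"
ARTIFACT = "artifact"
NO_PRESENCE = "no-presence"

#: Device vigilance states (4-state staging plus bookkeeping labels).
LIGHT_SLEEP = "LS"
DEEP_SLEEP = "DS"

REFERENCE_STAGES = (WAKE, N1, N2, N3, REM, ARTIFACT, NO_PRESENCE)
DEVICE_STAGES = (WAKE, LIGHT_SLEEP, DEEP_SLEEP, REM, ARTIFACT, NO_PRESENCE)

#: Stages counted as sleep on each side.
REFERENCE_SLEEP_STAGES = frozenset({N1, N2, N3, REM})
DEVICE_SLEEP_STAGES = frozenset({LIGHT_SLEEP, DEEP_SLEEP, REM})

#: Epochs carrying these labels are excluded from paired comparisons.
EXCLUDED_STAGES = frozenset({ARTIFACT, NO_PRESENCE})

#: Mapping from 5-state PSG staging to the devices' 4-state vocabulary.
REFERENCE_TO_DEVICE_STAGE = {
    WAKE: WAKE,
    N1: LIGHT_SLEEP,
    N2: LIGHT_SLEEP,
    N3: DEEP_SLEEP,
    REM: REM,
    ARTIFACT: ARTIFACT,
    NO_PRESENCE: NO_PRESENCE,
}


def _check_grid(epoch_start_s: np.ndarray, epoch_s: float) -> None:
    if epoch_start_s.ndim != 1 or epoch_start_s.size == 0:
        raise InputError("epoch grid must be a non-empty 1-d array")
    if epoch_s <= 0:
        raise InputError(f"epoch_s must be positive, got {epoch_s}")
    steps = np.diff(epoch_start_s)
    if steps.size and not np.allclose(steps, epoch_s, rtol=0, atol=1e-6):
        raise InputError("epoch grid must be strictly increasing with constant step epoch_s")


@dataclass
class EpochSeries:
    """Uniformly gridded per-epoch numeric values with missingness.

    Parameters
    ----------
    epoch_start_s : ndarray
        Left edge of each epoch, seconds from record start; strictly
        increasing with constant step ``epoch_s``.
    values : ndarray
        One value per epoch; NaN marks a missing estimate. Present values
        must be finite and strictly positive (rates are positive quantities).
    epoch_s : float
        Epoch length in seconds (30 for PSG-gridded series, 60 for devices
        reporting at minute resolution).
    unit : str
        ``"bpm"`` for heart rate, ``"cpm"`` for breathing rate.
    """

    epoch_start_s: np.ndarray
    values: np.ndarray
    epoch_s: float
    unit: str = "bpm"

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.epoch_start_s, self.epoch_s)
        if self.values.shape != self.epoch_start_s.shape:
            raise InputError("values and epoch_start_s must have the same shape")
        present = self.values[~np.isnan(self.values)]
        if present.size and (not np.all(np.isfinite(present)) or np.any(present <= 0)):
            raise InputError("present values must be finite and > 0")

    def __len__(self) -> int:
        return self.epoch_start_s.size

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def shift(self, lag_s: float) -> "EpochSeries":
        """Return a copy with all timestamps shifted by ``lag_s`` seconds."""
        return replace(self, epoch_start_s=self.epoch_start_s + lag_s,
                       values=self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_start_s": self.epoch_start_s, "value": self.values})


@dataclass
class Hypnogram:
    """Per-epoch categorical vigilance labels on a uniform grid.

    ``vocabulary`` declares which label set applies: the reference
    (PSG consensus) side uses the 5-stage AASM vocabulary plus artifact and
    no-presence; devices report 4-state staging (W / LS / DS / REM) plus the
    same bookkeeping labels.
    """

    epoch_start_s: np.ndarray
    stages: np.ndarray
    epoch_s: float
    vocabulary: tuple = REFERENCE_STAGES

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.stages = np.asarray(self.stages, dtype=object)
        _check_grid(self.epoch_start_s, self.epoch_s)
        if self.stages.shape != self.epoch_start_s.shape:
            raise InputError("stages and epoch_start_s must have the same shape")
        bad = set(self.stages.tolist()) - set(self.vocabulary)
        if bad:
            raise InputError(f"stage labels outside declared vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return self.epoch_start_s.size

    def shift(self, lag_s: float) -> "Hypnogram":
        return replace(self, epoch_start_s=self.epoch_start_s + lag_s,
                       stages=self.stages.copy())

    def is_sleep(self) -> np.ndarray:
        """Boolean mask of sleep epochs under this hypnogram's vocabulary."""
        sleep = (REFERENCE_SLEEP_STAGES if self.vocabulary == REFERENCE_STAGES
                 else DEVICE_SLEEP_STAGES)
        return np.isin(self.stages, list(sleep))

    def total_sleep_time_s(self) -> float:
        """Total sleep time: sleep-labelled epochs times epoch length."""
        return float(np.sum(self.is_sleep())) * self.epoch_s

    def to_device_vocabulary(self) -> "Hypnogram":
        """Map 5-state reference labels onto the 4-state device vocabulary."""
        mapped = np.array([REFERENCE_TO_DEVICE_STAGE[s] for s in self.stages],
                          dtype=object)
        return Hypnogram(self.epoch_start_s.copy(), mapped, self.epoch_s,
                         vocabulary=DEVICE_STAGES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_start_s": self.epoch_start_s, "stage": self.stages})


def epoch_grid(duration_s: float, epoch_s: float, start_s: float = 0.0) -> np.ndarray:
    """Left edges of the epochs tiling ``[start_s, start_s + duration_s)``."""
    n = int(round(duration_s / epoch_s))
    if abs(n * epoch_s - duration_s) > 1e-9:
        raise InputError("epoch_s must divide duration_s")
    return start_s + epoch_s * np.arange(n, dtype=float)


def epoch_index(times_s: Iterable[float], grid_start_s: float, epoch_s: float) -> np.ndarray:
    """Index of the epoch containing each time (half-open intervals)."""
    t = np.asarray(list(times_s) if not isinstance(times_s, np.ndarray) else times_s,
                   dtype=float)
    return np.floor((t - grid_start_s) / epoch_s).astype(int)


@dataclass
class Waveform:
    """A uniformly sampled continuous trace (respiration or snore intensity)."""

    fs: float
    values: np.ndarray
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.values.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


@dataclass
class BinarySeries:
    """Per-epoch boolean channel (e.g. device-detected snore presence)."""

    epoch_start_s: np.ndarray
    values: np.ndarray
    epoch_s: float

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.values = np.asarray(self.values, dtype=bool)
        _check_grid(self.epoch_start_s, self.epoch_s)
        if self.values.shape != self.epoch_start_s.shape:
            raise InputError("values and epoch_start_s must have the same shape")

    def __len__(self) -> int:
        return self.epoch_start_s.size
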