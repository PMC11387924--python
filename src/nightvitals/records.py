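"""Per-night data bundles: reference channels plus device channels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .epochs import BinarySeries, EpochSeries, Hypnogram, Waveform
from .errors import InputError
from .events import EventList


@dataclass
class DeviceNight:
    """One device's channels for one participant-night."""

    device: str
    hr: Optional[EpochSeries] = None
    br: Optional[EpochSeries] = None
    hypnogram: Optional[Hypnogram] = None
    snore_epochs: Optional[BinarySeries] = None
    ahi: Optional[float] = None
    bdi: Optional[float] = None


@dataclass
class NightRecord:
    """One participant-night: reference channels, events, device channels.

    Laboratory records carry the full polysomnography reference (beat
    timestamps, respiration waveform, consensus hypnogram, snore-intensity
    trace, scored respiratory events); home records may omit them.
    """

    participant_id: str
    setting: str = "lab"
    beats_s: Optional[np.ndarray] = None
    respiration: Optional[Waveform] = None
    #: pre-extracted reference epoch series; when present they take
    #: precedence over re-deriving rates from the raw channels
    ref_hr: Optional[EpochSeries] = None
    ref_br: Optional[EpochSeries] = None
    hypnogram: Optional[Hypnogram] = None
    snore_trace: Optional[Waveform] = None
    events: Optional[EventList] = None
    lights_off_s: float = 0.0
    lights_on_s: float = 0.0
    devices: Dict[str, DeviceNight] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.setting not in ("lab", "home"):
            raise InputError(f"setting must be 'lab' or 'home', got {self.setting!r}")
        if self.lights_on_s <= self.lights_off_s:
            raise InputError("lights_off_s must precede lights_on_s")
        if self.setting == "lab" and self.hypnogram is None:
            raise InputError("lab records must carry a reference hypnogram")

    def device(self, name: str) -> DeviceNight:
        try:
            return self.devices[name]
        except KeyError:
            raise InputError(
                f"participant {self.participant_id!r} has no channels for device {name!r}"
            ) from None
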