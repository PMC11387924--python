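"""Breathing-disturbance and snore event lists."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import InputError

APNEA = "apnea"
HYPOPNEA = "hypopnea"
SNORE = "snore"
EVENT_TYPES = (APNEA, HYPOPNEA, SNORE)


@dataclass(frozen=True)
class Event:
    """One scored event: an apnea, a hypopnea, or a snore episode.

    ``intensity_db`` is only meaningful for snore events (sound level above
    the ambient baseline); it is ``None`` for respiratory events.
    """

    type: str
    start_s: float
    duration_s: float
    intensity_db: Optional[float] = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise InputError(f"unknown event type {self.type!r}")
        if self.duration_s <= 0:
            raise InputError("event duration must be > 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class EventList:
    """Events of one night, sorted by start time and bounded by the night."""

    events: list = field(default_factory=list)
    night_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start_s, e.end_s))
        for ev in self.events:
            if ev.start_s < 0:
                raise InputError("event starts before the record")
            if self.night_duration_s is not None and ev.end_s > self.night_duration_s + 1e-9:
                raise InputError("event extends past the end of the night")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def of_type(self, *types: str) -> "EventList":
        return EventList([e for e in self.events if e.type in types],
                         night_duration_s=self.night_duration_s)

    @property
    def respiratory(self) -> "EventList":
        return self.of_type(APNEA, HYPOPNEA)

    @property
    def snores(self) -> "EventList":
        return self.of_type(SNORE)

    def total_duration_s(self, merge_overlaps: bool = True) -> float:
        """Summed event duration; overlapping events are merged first by
        default so a second overlapping score does not double-count time."""
        if not self.events:
            return 0.0
        if not merge_overlaps:
            return float(sum(e.duration_s for e in self.events))
        total = 0.0
        cur_start, cur_end = self.events[0].start_s, self.events[0].end_s
        for ev in self.events[1:]:
            if ev.start_s <= cur_end:
                cur_end = max(cur_end, ev.end_s)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = ev.start_s, ev.end_s
        total += cur_end - cur_start
        return total
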