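"""Shared timed-event plumbing for volume (hemorrhage/infusion) schedules."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VolumeEvent", "validate_events", "events_rate_at"]


@dataclass(frozen=True)
class VolumeEvent:
    """A timed volume change expressed as a fraction of baseline blood volume."""

    start: float       # min
    duration: float    # min
    fraction: float    # of baseline blood volume, in [0, 0.6]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if not (0.0 <= self.fraction <= 0.6):
            raise ValueError("volume fraction must lie in [0, 0.6]")
        if self.start < 0:
            raise ValueError("event start must be nonnegative")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        """Fraction of baseline blood volume per minute."""
        return self.fraction / self.duration


def validate_events(events: list[VolumeEvent], kind: str) -> list[VolumeEvent]:
    events = sorted(events, key=lambda e: e.start)
    for a, b in zip(events, events[1:]):
        if b.start < a.end - 1e-12:
            raise ValueError(f"{kind} events overlap")
    return events


def events_rate_at(events: list[VolumeEvent], t: float) -> float:
    for e in events:
        if e.start <= t < e.end:
            return e.rate
    return 0.0
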