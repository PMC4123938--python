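"""Observation schedule: the daily 30-minute video-decoding windows.

Behavior was scored from video over ten 30-min windows per day, one every
hour and a half through the lights-on period, with the dark period
(21:00-06:00) omitted.  Times are seconds since the study epoch, which is
midnight of the first observation day; the schedule repeats daily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DAY = 86_400
#: Daily windows as (start, end) seconds-of-day: 06:00-06:30 ... 19:30-20:00.
DEFAULT_WINDOW_STARTS_H = (6.0, 7.5, 9.0, 10.5, 12.0, 13.5, 15.0, 16.5, 18.0, 19.5)
WINDOW_LEN = 1800


def _default_windows() -> tuple[tuple[int, int], ...]:
    return tuple(
        (int(h * 3600), int(h * 3600) + WINDOW_LEN) for h in DEFAULT_WINDOW_STARTS_H
    )


@dataclass(frozen=True)
class ObservationSchedule:
    """Daily observation windows, repeated for ``n_days`` days.

    ``windows`` holds (start, end) seconds-of-day pairs; they must be
    non-overlapping and sorted.  The default is the ten 30-min windows of
    the study protocol over a 48-h (2-day) recording.
    """

    windows: tuple[tuple[int, int], ...] = field(default_factory=_default_windows)
    n_days: int = 2
    lights_on: tuple[int, int] = (6 * 3600, 21 * 3600)  # dark 21:00-06:00 excluded

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.windows:
            if end <= start:
                raise ValueError("window end must be after start")
            if prev_end is not None and start < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            if not (self.lights_on[0] <= start and end <= self.lights_on[1]):
                raise ValueError("window falls in the dark period")
            prev_end = end
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    def absolute_windows(self) -> list[tuple[int, int]]:
        """All (start, end) windows in absolute seconds since the epoch."""
        out = []
        for day in range(self.n_days):
            for start, end in self.windows:
                out.append((day * DAY + start, day * DAY + end))
        return out

    def contains(self, t: float) -> bool:
        """True if t (seconds since epoch) falls inside an observation window."""
        tod = t % DAY
        if not 0 <= t < self.n_days * DAY:
            return False
        return any(start <= tod < end for start, end in self.windows)

    @property
    def total_observed_seconds(self) -> int:
        """Scheduled observation time across all days (36 000 s by default)."""
        return self.n_days * sum(end - start for start, end in self.windows)

    @property
    def span(self) -> tuple[int, int]:
        """(first window start, last window end) in absolute seconds."""
        aw = self.absolute_windows()
        return (aw[0][0], aw[-1][1])
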