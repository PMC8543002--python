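"""Lap/segment structure of a varying-terrain treadmill session.

A session consists of ``laps`` identical laps, each tiled by an ordered list
of terrain segments (incline + intensity-dependent speed + duration).  The
session clock starts at 0 s and time windows follow the half-open
``[start, end)`` convention, so every instant of the session belongs to
exactly one (lap, segment) window.

The simulated downhill (last segment) is special: the treadmill runs it at a
safe speed while the skier holds a rope in a tuck, so whole-session distance
and mean speed are reported with a more realistic *display* speed
substituted for that segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ProtocolError",
    "SegmentSpec",
    "SegmentWindow",
    "ProtocolDefinition",
    "build_protocol",
    "default_protocol",
    "load_protocol",
    "segment_at",
    "session_distance_and_speed",
]

INTENSITIES = ("LI", "HI")


class ProtocolError(ValueError):
    """Raised when a protocol configuration is inconsistent."""


@dataclass(frozen=True)
class SegmentSpec:
    """One terrain segment of a lap.

    Parameters
    ----------
    index : int
        1-based position of the segment within the lap.
    incline : float
        Treadmill grade as a fraction (rise/run); 0.05 means 5 %.
    speed_li, speed_hi : float
        Belt speed in km/h at low and high intensity.
    duration : float
        Segment duration in seconds.
    """

    index: int
    incline: float
    speed_li: float
    speed_hi: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError(
                f"segment {self.index}: duration must be > 0, got {self.duration}"
            )
        if not -0.20 <= self.incline <= 0.20:
            raise ProtocolError(
                f"segment {self.index}: incline {self.incline} outside [-0.20, 0.20]"
            )
        if self.speed_li <= 0 or self.speed_hi <= 0:
            raise ProtocolError(f"segment {self.index}: speeds must be > 0")

    def speed(self, intensity: str) -> float:
        _check_intensity(intensity)
        return self.speed_li if intensity == "LI" else self.speed_hi


@dataclass(frozen=True)
class SegmentWindow:
    """A concrete (lap, segment) time window on the session clock."""

    lap: int
    segment: int
    start: float
    end: float


@dataclass(frozen=True)
class ProtocolDefinition:
    """Validated session schedule: ``laps`` repetitions of the segment list."""

    laps: int
    segments: tuple[SegmentSpec, ...]
    lap_duration: float
    downhill_display_speed_li: float
    downhill_display_speed_hi: float

    @property
    def total_duration(self) -> float:
        """Whole-session duration in seconds."""
        return self.laps * self.lap_duration

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_offsets(self) -> np.ndarray:
        """Start offset of each segment within a lap (seconds)."""
        durations = [s.duration for s in self.segments]
        return np.concatenate([[0.0], np.cumsum(durations)[:-1]])

    def windows(self) -> list[SegmentWindow]:
        """All (lap, segment) windows tiling ``[0, total_duration)``."""
        offsets = self.segment_offsets()
        out = []
        for lap in range(1, self.laps + 1):
            lap_start = (lap - 1) * self.lap_duration
            for seg, off in zip(self.segments, offsets):
                out.append(
                    SegmentWindow(
                        lap=lap,
                        segment=seg.index,
                        start=lap_start + off,
                        end=lap_start + off + seg.duration,
                    )
                )
        return out

    def lap_windows(self) -> list[tuple[int, float, float]]:
        """(lap, start, end) for each lap."""
        return [
            (lap, (lap - 1) * self.lap_duration, lap * self.lap_duration)
            for lap in range(1, self.laps + 1)
        ]

    def downhill_display_speed(self, intensity: str) -> float:
        _check_intensity(intensity)
        return (
            self.downhill_display_speed_li
            if intensity == "LI"
            else self.downhill_display_speed_hi
        )

    def lap_segment_at(self, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (lap, segment index) lookup; half-open windows."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t >= self.total_duration):
            raise ProtocolError(
                f"time outside [0, {self.total_duration}) s session window"
            )
        lap = (t // self.lap_duration).astype(int) + 1
        t_in_lap = t - (lap - 1) * self.lap_duration
        offsets = self.segment_offsets()
        seg_idx = np.searchsorted(offsets, t_in_lap, side="right") - 1
        segment = np.array([self.segments[i].index for i in range(self.n_segments)])[
            seg_idx
        ]
        return lap, segment

    def speed_kmh_at(
        self, t: float | np.ndarray, intensity: str, display: bool = False
    ) -> np.ndarray:
        """Belt speed (km/h) at time(s) ``t``.

        With ``display=True`` the downhill display speed replaces the last
        segment's treadmill speed (used for distance/mean-speed reporting).
        """
        _check_intensity(intensity)
        _, segment = self.lap_segment_at(t)
        speeds = np.array([s.speed(intensity) for s in self.segments])
        if display:
            speeds = speeds.copy()
            speeds[-1] = self.downhill_display_speed(intensity)
        index_of = {s.index: i for i, s in enumerate(self.segments)}
        pos = np.vectorize(index_of.get)(segment)
        return speeds[pos]

    def incline_at(self, t: float | np.ndarray) -> np.ndarray:
        """Grade fraction at time(s) ``t``."""
        _, segment = self.lap_segment_at(t)
        grades = {s.index: s.incline for s in self.segments}
        return np.vectorize(grades.get)(segment)


def _check_intensity(intensity: str) -> None:
    if intensity not in INTENSITIES:
        raise ProtocolError(f"intensity must be one of {INTENSITIES}, got {intensity!r}")


def build_protocol(config: Mapping) -> ProtocolDefinition:
    """Validate a key-value protocol document into a :class:`ProtocolDefinition`.

    The document uses the keys ``laps``, ``lap_duration_s``,
    ``downhill_display_speed_{li,hi}_kmh`` and a ``segments`` list of
    ``{incline_pct, speed_li_kmh, speed_hi_kmh, duration_s}`` mappings.

    Raises
    ------
    ProtocolError
        Naming the offending field when a segment is missing, a duration is
        nonpositive, or segment durations do not sum to ``lap_duration_s``.
    """
    for key in ("laps", "lap_duration_s", "segments"):
        if key not in config:
            raise ProtocolError(f"missing required key {key!r}")
    raw_segments: Sequence[Mapping] = config["segments"]
    if len(raw_segments) < 1:
        raise ProtocolError("segments: at least one segment is required")
    segments = []
    for i, raw in enumerate(raw_segments, start=1):
        for key in ("incline_pct", "speed_li_kmh", "speed_hi_kmh", "duration_s"):
            if key not in raw:
                raise ProtocolError(f"segment {i}: missing field {key!r}")
        segments.append(
            SegmentSpec(
                index=i,
                incline=float(raw["incline_pct"]) / 100.0,
                speed_li=float(raw["speed_li_kmh"]),
                speed_hi=float(raw["speed_hi_kmh"]),
                duration=float(raw["duration_s"]),
            )
        )
    lap_duration = float(config["lap_duration_s"])
    total = sum(s.duration for s in segments)
    if not np.isclose(total, lap_duration, atol=1e-9):
        raise ProtocolError(
            f"segments: durations sum to {total} s, lap_duration_s is {lap_duration} s"
        )
    laps = int(config["laps"])
    if laps < 1:
        raise ProtocolError("laps: must be >= 1")
    last = segments[-1]
    return ProtocolDefinition(
        laps=laps,
        segments=tuple(segments),
        lap_duration=lap_duration,
        downhill_display_speed_li=float(
            config.get("downhill_display_speed_li_kmh", last.speed_li)
        ),
        downhill_display_speed_hi=float(
            config.get("downhill_display_speed_hi_kmh", last.speed_hi)
        ),
    )


def load_protocol(path) -> ProtocolDefinition:
    """Read a YAML/JSON protocol document from ``path`` and validate it."""
    with open(path) as fh:
        return build_protocol(yaml.safe_load(fh))


def default_protocol() -> ProtocolDefinition:
    """The packaged 7 x 180 s varying-terrain schedule.

    Calibrated so that the time-weighted mean speed with the downhill
    display-speed substitution is 16.7 km/h (LI) and 21.3 km/h (HI).
    """
    text = resources.files("skifuse.data").joinpath("default_protocol.yaml").read_text()
    return build_protocol(yaml.safe_load(text))


def segment_at(protocol: ProtocolDefinition, t: float) -> SegmentWindow:
    """The unique (lap, segment) window containing session time ``t``.

    Windows are half-open, so ``t`` equal to the total duration is out of
    range.
    """
    lap, segment = protocol.lap_segment_at(float(t))
    lap_i, seg_i = int(lap), int(segment)
    offsets = protocol.segment_offsets()
    pos = [s.index for s in protocol.segments].index(seg_i)
    start = (lap_i - 1) * protocol.lap_duration + offsets[pos]
    return SegmentWindow(
        lap=lap_i,
        segment=seg_i,
        start=float(start),
        end=float(start + protocol.segments[pos].duration),
    )


def session_distance_and_speed(
    protocol: ProtocolDefinition, intensity: str
) -> tuple[float, float]:
    """Whole-session distance (km) and mean speed (km/h), one decimal.

    Distance is the time-weighted sum of segment speeds over all laps with
    the downhill display speed substituted for the last segment; mean speed
    is distance over total duration.
    """
    _check_intensity(intensity)
    speeds = [s.speed(intensity) for s in protocol.segments]
    speeds[-1] = protocol.downhill_display_speed(intensity)
    per_lap_km = sum(v * s.duration for v, s in zip(speeds, protocol.segments)) / 3600.0
    distance = protocol.laps * per_lap_km
    mean_speed = distance / (protocol.total_duration / 3600.0)
    return round(distance, 1), round(mean_speed, 1)
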