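"""Sensor-stream containers, CSV round-trip, synchronization and the 1 Hz
master timeline.

Every device produces a uniformly sampled :class:`SensorStream`.  Streams are
aligned to a common master clock (``t0`` is the offset added to file-local
timestamps), reduced to per-second means (2-s means for the oximetry
streams) and merged with the cycle-level biomechanics into one tidy table
with one row per session second — the master timeline all summary statistics
are computed from.

Missing data are explicit ``NaN`` markers, never zeros, so seconds without a
measurement (e.g. the even laps on which the motion-capture system did not
record) do not bias aggregate means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import ProtocolDefinition, _check_intensity

__all__ = [
    "StreamFormatError",
    "SyncDetectionError",
    "CoverageError",
    "SensorStream",
    "read_stream",
    "write_stream",
    "detect_sync_jumps",
    "resample_1hz",
    "build_master_timeline",
    "moving_average",
    "MASTER_COLUMNS",
]

PLACEMENTS = ("chest", "wrist_L", "wrist_R", "ski_L", "ski_R", "pole_L",
              "pole_R", "markers", "hr", "vo2", "tsi_arm", "tsi_leg")

#: Analysis columns of the master timeline, plus lap/segment/intensity.
MASTER_COLUMNS = [
    "pct_hr", "pct_vo2", "tsi_leg", "tsi_arm", "cl_m", "cr_cpm",
    "sub_technique", "ct_pole_s", "ct_ski_s", "p_cycle_w", "pct_p_pole",
    "pct_p_ski", "pct_p_pole_left", "pct_p_pole_right",
]


class StreamFormatError(ValueError):
    """Malformed stream file or non-uniform timestamps."""


class SyncDetectionError(RuntimeError):
    """Fewer synchronization jumps found than expected."""

    def __init__(self, found: int, expected: int = 3):
        self.found = found
        self.expected = expected
        super().__init__(f"found {found} synchronization jumps, expected {expected}")


class CoverageError(ValueError):
    """A stream does not cover the full session."""


@dataclass
class SensorStream:
    """One uniformly sampled signal from one device placement.

    ``data`` holds a ``time_s`` column (file-local clock) plus one column
    per channel; ``t0`` is the offset to the master clock, i.e. master time
    = ``time_s + t0``.
    """

    placement: str
    rate: float
    data: pd.DataFrame
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise StreamFormatError(f"rate must be > 0, got {self.rate}")
        if "time_s" not in self.data.columns:
            raise StreamFormatError("stream data must have a time_s column")
        if len(self.data.columns) < 2:
            raise StreamFormatError("stream needs at least one channel column")
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) >= 2:
            dt = np.diff(t)
            period = 1.0 / self.rate
            if np.any(np.abs(dt - period) > 0.1 * period):
                raise StreamFormatError(
                    f"{self.placement}: non-uniform timestamps "
                    f"(jitter > 10% of the {period:.6g} s sample period)"
                )

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c != "time_s"]

    @property
    def master_time(self) -> np.ndarray:
        """Timestamps on the master clock."""
        return self.data["time_s"].to_numpy(dtype=float) + self.t0

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def write_stream(stream: SensorStream, path) -> None:
    """Write a stream as CSV with a small metadata header (``# key: value``)."""
    with open(path, "w") as fh:
        fh.write(f"# placement: {stream.placement}\n")
        fh.write(f"# rate_hz: {stream.rate!r}\n")
        fh.write(f"# t0_s: {stream.t0!r}\n")
        stream.data.to_csv(fh, index=False, float_format="%.9g")


def read_stream(path, placement: str | None = None) -> SensorStream:
    """Read a stream CSV written by :func:`write_stream`.

    ``placement`` overrides the header value if given.  Raises
    :class:`StreamFormatError` on missing columns or non-uniform timestamps.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    if "time_s" not in frame.columns:
        raise StreamFormatError(f"{path}: missing time_s column")
    if len(frame.columns) < 2:
        raise StreamFormatError(f"{path}: no channel columns")
    placement = placement or meta.get("placement", "unknown")
    rate = float(meta.get("rate_hz", "nan"))
    if not np.isfinite(rate):
        t = frame["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise StreamFormatError(f"{path}: cannot infer sampling rate")
        rate = 1.0 / float(np.median(np.diff(t)))
    return SensorStream(
        placement=placement,
        rate=rate,
        data=frame,
        t0=float(meta.get("t0_s", 0.0)),
    )


def detect_sync_jumps(
    chest: SensorStream,
    axis: str = "acc_z",
    calibration_window_s: float = 10.0,
    threshold_mads: float = 5.0,
    refractory_s: float = 0.5,
    n_expected: int = 3,
) -> np.ndarray:
    """Locate the synchronization jumps in the pre-session calibration window.

    Peaks of the vertical-axis deviation from its median exceeding
    ``threshold_mads`` robust standard deviations, separated by at least
    ``refractory_s``.  Returns exactly ``n_expected`` file-local peak times
    sorted ascending (the largest peaks if more qualify) or raises
    :class:`SyncDetectionError` reporting how many were found.
    """
    from scipy.signal import find_peaks

    t = chest.data["time_s"].to_numpy(dtype=float)
    x = chest.channel(axis)
    m = t < t[0] + calibration_window_s
    if not np.any(m):
        raise SyncDetectionError(0, n_expected)
    tw, xw = t[m], x[m]
    dev = np.abs(xw - np.median(xw))
    mad = np.median(np.abs(dev - np.median(dev)))
    robust_sd = 1.4826 * mad if mad > 0 else np.std(dev) or 1e-12
    threshold = np.median(dev) + threshold_mads * robust_sd
    peaks, props = find_peaks(
        dev, height=threshold, distance=max(1, int(refractory_s * chest.rate))
    )
    if len(peaks) < n_expected:
        raise SyncDetectionError(len(peaks), n_expected)
    if len(peaks) > n_expected:
        order = np.argsort(props["peak_heights"])[::-1][:n_expected]
        peaks = np.sort(peaks[order])
    return tw[peaks]


def resample_1hz(
    stream: SensorStream,
    window: int = 1,
    channel: str | None = None,
    t_start: float = 0.0,
    n_seconds: int | None = None,
) -> np.ndarray:
    """Reduce a stream to per-second values on the master clock.

    The value at second ``k`` is the mean of the samples whose master time
    falls in ``[k, k + window)``; ``window`` is 1 s for all streams except
    the oximetry streams, which use 2 s.  Seconds with no samples are
    ``NaN``.
    """
    if window not in (1, 2):
        raise ValueError(f"window must be 1 or 2 s, got {window}")
    channel = channel or stream.channels[0]
    t = stream.master_time
    x = stream.channel(channel)
    if n_seconds is None:
        n_seconds = int(np.floor(t[-1] - t_start)) + 1
    sec = np.floor(t - t_start).astype(int)
    valid = (sec >= 0) & (sec < n_seconds) & np.isfinite(x)
    sums = np.bincount(sec[valid], weights=x[valid], minlength=n_seconds)
    counts = np.bincount(sec[valid], minlength=n_seconds)
    if window == 2:
        sums = sums + np.concatenate([sums[1:], [0.0]])
        counts = counts + np.concatenate([counts[1:], [0]])
    out = np.full(n_seconds, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def _broadcast_cycles(
    cycle_table: pd.DataFrame,
    columns: Sequence[str],
    n_seconds: int,
) -> dict[str, np.ndarray]:
    """Broadcast cycle-level values to the seconds each cycle spans.

    Second ``k`` takes the value of the cycle whose ``[start, end)`` window
    contains the second's midpoint ``k + 0.5``.
    """
    mid = np.arange(n_seconds) + 0.5
    starts = cycle_table["start"].to_numpy(dtype=float)
    ends = cycle_table["end"].to_numpy(dtype=float)
    idx = np.searchsorted(starts, mid, side="right") - 1
    ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(ends) - 1)])
    out: dict[str, np.ndarray] = {}
    for col in columns:
        vals = cycle_table[col].to_numpy()
        if vals.dtype.kind in "fiu":
            arr = np.full(n_seconds, np.nan)
            arr[ok] = vals[idx[ok]].astype(float)
        else:
            arr = np.full(n_seconds, None, dtype=object)
            arr[ok] = vals[idx[ok]]
        out[col] = arr
    return out


def build_master_timeline(
    protocol: ProtocolDefinition,
    intensity: str,
    hr_max: float,
    vo2max: float,
    hr: SensorStream | None = None,
    vo2: SensorStream | None = None,
    tsi_leg: SensorStream | None = None,
    tsi_arm: SensorStream | None = None,
    cycle_table: pd.DataFrame | None = None,
    odd_lap_power_only: bool = True,
) -> pd.DataFrame:
    """Merge all per-second and cycle-level variables into one 1 Hz table.

    One row per session second with lap/segment annotation.  ``%HR`` and
    ``%VO2`` are percentages of the individual maxima; the 10-s
    mixing-chamber oxygen-uptake values are step-held across their interval
    before the merge; oximetry uses 2-s means.  Cycle-level quantities
    (``cycle_table`` columns ``label``, ``cl_m``, ``cr_cpm`` and optional
    contact/power columns) are broadcast to the seconds their cycle spans.
    Power columns on laps the motion-capture system did not record (the even
    laps, when ``odd_lap_power_only``) carry missing markers.
    """
    _check_intensity(intensity)
    n_seconds = int(protocol.total_duration)
    sec = np.arange(n_seconds, dtype=float)
    lap, segment = protocol.lap_segment_at(sec)
    out = pd.DataFrame({"time_s": sec, "lap": lap, "segment": segment})
    out["intensity"] = intensity

    def _per_second(stream: SensorStream | None, window: int = 1) -> np.ndarray:
        if stream is None:
            return np.full(n_seconds, np.nan)
        t = stream.master_time
        if t[0] > 0.0 or t[-1] < n_seconds - 1 - 1.0 / stream.rate - 1e-9:
            span_needed = n_seconds - 1
            if t[-1] < span_needed - max(10.0, 1.0 / stream.rate):
                raise CoverageError(
                    f"{stream.placement}: stream ends at {t[-1]:.1f} s, "
                    f"session lasts {n_seconds} s"
                )
        return resample_1hz(stream, window=window, n_seconds=n_seconds)

    if vo2 is not None:
        # step-hold each 10-s mixing-chamber value across its interval
        t = vo2.master_time
        vals = vo2.channel(vo2.channels[0])
        if t[-1] < n_seconds - 15.0:
            raise CoverageError(
                f"vo2: stream ends at {t[-1]:.1f} s, session lasts {n_seconds} s"
            )
        idx = np.clip(np.searchsorted(t, sec, side="right") - 1, 0, len(vals) - 1)
        vo2_per_sec = vals[idx]
    else:
        vo2_per_sec = np.full(n_seconds, np.nan)

    out["pct_hr"] = 100.0 * _per_second(hr) / hr_max
    out["pct_vo2"] = 100.0 * vo2_per_sec / vo2max
    out["tsi_leg"] = _per_second(tsi_leg, window=2)
    out["tsi_arm"] = _per_second(tsi_arm, window=2)

    cycle_cols = {
        "label": "sub_technique", "cl_m": "cl_m", "cr_cpm": "cr_cpm",
        "ct_pole_s": "ct_pole_s", "ct_ski_s": "ct_ski_s",
        "p_cycle_w": "p_cycle_w", "pct_p_pole": "pct_p_pole",
        "pct_p_ski": "pct_p_ski", "pct_p_pole_left": "pct_p_pole_left",
        "pct_p_pole_right": "pct_p_pole_right",
    }
    if cycle_table is not None and len(cycle_table):
        present = [c for c in cycle_cols if c in cycle_table.columns]
        broadcast = _broadcast_cycles(cycle_table, present, n_seconds)
        for src in present:
            out[cycle_cols[src]] = broadcast[src]
    for col in MASTER_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan if col != "sub_technique" else None

    if odd_lap_power_only:
        even = out["lap"] % 2 == 0
        for col in ("p_cycle_w", "pct_p_pole", "pct_p_ski",
                    "pct_p_pole_left", "pct_p_pole_right"):
            out.loc[even, col] = np.nan
    return out[["time_s", "lap", "segment", "intensity"] + MASTER_COLUMNS]


def moving_average(values: np.ndarray, window_s: int = 30) -> np.ndarray:
    """Centered moving average for plotting smoothed per-second traces
    (e.g. a 30-s oxygen-uptake trace); NaNs are ignored within each window."""
    s = pd.Series(values)
    return s.rolling(window_s, center=True, min_periods=1).mean().to_numpy()
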