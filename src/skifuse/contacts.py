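"""Pole and ski ground-contact detection from wrist and ski inertial units.

Pole contact: the plant excites a high-frequency vibration of the wrist
accelerometer, so initial contact is the first acceleration peak at the
onset of that vibration; terminal contact is the largest acceleration peak
close to the minimum of the angular speed, where the arm reverses to bring
the pole back.

Ski contact: while the ski is on the ground its pitch rotation is quiet, so
ground contact shows up as a long low-angular-velocity phase.  Initial
contact is the last pitch-rate peak preceding that phase and terminal
contact the last negative vertical-acceleration peak just after it.

All accelerometer channels are median-centred before use, which makes the
detectors exactly invariant to constant (gravity) offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .streams_io import SensorStream

__all__ = [
    "ContactEvent",
    "detect_pole_contacts",
    "detect_ski_contacts",
    "contact_metrics",
    "events_frame",
]

ACC_CHANNELS = ("acc_x", "acc_y", "acc_z")
GYRO_CHANNELS = ("gyro_x", "gyro_y", "gyro_z")


@dataclass(frozen=True)
class ContactEvent:
    """One ground-contact interval of a pole or ski."""

    kind: str  # "pole" | "ski"
    side: str  # "L" | "R"
    initial: float
    terminal: float

    def __post_init__(self) -> None:
        if self.terminal <= self.initial:
            raise ValueError("terminal contact must follow initial contact")

    @property
    def contact_time(self) -> float:
        return self.terminal - self.initial


def events_frame(events: list[ContactEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "side": [e.side for e in events],
            "initial": [e.initial for e in events],
            "terminal": [e.terminal for e in events],
        }
    )


def _centered_magnitude(stream: SensorStream, channels=ACC_CHANNELS) -> np.ndarray:
    comps = []
    for ch in channels:
        x = stream.channel(ch)
        comps.append(x - np.median(x))
    return np.linalg.norm(np.column_stack(comps), axis=1)


def detect_pole_contacts(
    wrist: SensorStream,
    side: str = "L",
    band_hz: tuple[float, float] = (20.0, 60.0),
    energy_window_s: float = 0.02,
    threshold_factor: float = 4.0,
    terminal_window_s: float = 0.075,
    min_gap_s: float = 0.25,
    t_start: float = 0.0,
) -> list[ContactEvent]:
    """Pole contact events from a wrist accelerometer + gyroscope stream.

    Vibration onset is located by a moving-SD envelope (``energy_window_s``)
    of the 20-60 Hz band of the acceleration magnitude crossing
    ``threshold_factor`` robust standard deviations above its baseline; the
    initial contact is the first acceleration-magnitude peak at that onset.
    Terminal contact is the acceleration-magnitude argmax within
    ``±terminal_window_s`` of the first local minimum of the smoothed
    angular-speed magnitude following the initial contact.  Poling actions
    whose terminal search window is empty are skipped with a warning.
    """
    t = wrist.master_time
    rate = wrist.rate
    mag = _centered_magnitude(wrist)
    gyro_mag = _centered_magnitude(wrist, GYRO_CHANNELS)
    gyro_smooth = gaussian_filter1d(gyro_mag, max(1.0, 0.01 * rate))

    sos = butter(4, band_hz, btype="bandpass", fs=rate, output="sos")
    band = sosfiltfilt(sos, mag)
    win = max(3, int(energy_window_s * rate))
    env = np.sqrt(np.clip(uniform_filter1d(band**2, win), 0.0, None))
    baseline = np.median(env)
    mad = np.median(np.abs(env - baseline))
    robust_sd = 1.4826 * mad if mad > 0 else (np.std(env) or 1e-12)
    threshold = baseline + threshold_factor * robust_sd

    above = env > threshold
    # contiguous vibration regions, merging gaps shorter than 30 ms and
    # dropping isolated noise crossings (too short or too weak)
    regions: list[tuple[int, int]] = []
    idx = np.flatnonzero(above)
    if len(idx):
        gap = int(0.03 * rate)
        min_len = max(2, int(0.008 * rate))
        run_start = idx[0]
        prev = idx[0]
        for k in idx[1:]:
            if k - prev > gap:
                regions.append((run_start, prev))
                run_start = k
            prev = k
        regions.append((run_start, prev))
        regions = [
            (r0, r1) for r0, r1 in regions
            if r1 - r0 + 1 >= min_len
            and np.max(env[r0:r1 + 1]) >= threshold + 0.5 * (threshold - baseline)
        ]

    # minima of the angular-speed magnitude (arm reversal candidates)
    gyro_minima, _ = find_peaks(-gyro_smooth, distance=max(1, int(0.1 * rate)))
    gyro_min_times = t[gyro_minima]

    events: list[ContactEvent] = []
    skipped = 0
    last_initial = -np.inf
    last_terminal = -np.inf
    for r0, r1 in regions:
        if t[r0] < t_start:
            continue
        if t[r0] < last_terminal + 0.05:
            continue  # still inside the previous poling action
        # refine the onset to where the envelope reaches a fraction of the
        # regional peak (filter ringing can leak past a low threshold)
        peak_env = float(np.max(env[r0:r1 + 1]))
        onset_level = max(threshold, 0.15 * peak_env)
        shift = np.flatnonzero(env[r0:r1 + 1] >= onset_level)
        if len(shift):
            r0 = r0 + int(shift[0])
        # first acceleration peak at the beginning of the vibration region
        s0 = max(0, r0 - int(0.01 * rate))
        s1 = min(len(t), r0 + int(0.05 * rate))
        local_scale = float(np.max(mag[s0:s1]) - np.median(mag[s0:s1]))
        peaks, _ = find_peaks(mag[s0:s1], prominence=0.3 * local_scale)
        if len(peaks) == 0:
            peaks = np.array([int(np.argmax(mag[s0:s1]))])
        initial = t[s0 + peaks[0]]
        if initial - last_initial < min_gap_s:
            continue
        # first angular-speed minimum after the plant
        after = gyro_min_times[gyro_min_times > initial + 0.05]
        if len(after) == 0:
            skipped += 1
            continue
        t_min = after[0]
        w0 = int(np.searchsorted(t, t_min - terminal_window_s))
        w1 = int(np.searchsorted(t, t_min + terminal_window_s))
        if w1 <= w0:
            skipped += 1
            continue
        terminal = t[w0 + int(np.argmax(mag[w0:w1]))]
        if terminal <= initial:
            skipped += 1
            continue
        events.append(ContactEvent("pole", side, float(initial), float(terminal)))
        last_initial = initial
        last_terminal = terminal
    if skipped:
        warnings.warn(f"pole contact detection skipped {skipped} poling actions")
    return events


def detect_ski_contacts(
    ski: SensorStream,
    side: str = "L",
    pitch_channel: str = "gyro_y",
    low_threshold_dps: float = 30.0,
    min_dwell_s: float = 0.1,
    peak_search_s: float = 0.12,
    t_start: float = 0.0,
) -> list[ContactEvent]:
    """Ski contact events from a ski-mounted accelerometer + gyroscope.

    Low-angular-velocity phases are runs of ``|pitch rate| <
    low_threshold_dps`` lasting at least ``min_dwell_s``.  Initial contact
    is the last pitch-rate peak preceding each phase; terminal contact the
    last negative vertical-acceleration peak within ``peak_search_s`` after
    the phase, before the swing rotation resumes.  Continuous rotation
    (no low phase) yields an empty list.
    """
    t = ski.master_time
    rate = ski.rate
    pitch = np.abs(gaussian_filter1d(ski.channel(pitch_channel), max(1.0, 0.005 * rate)))
    z = ski.channel("acc_z")
    neg_z = -(z - np.median(z))

    low = pitch < low_threshold_dps
    idx = np.flatnonzero(low)
    if len(idx) == 0:
        return []
    min_run = int(min_dwell_s * rate)
    phases: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    for k in idx[1:]:
        if k - prev > 1:
            if prev - run_start >= min_run:
                phases.append((run_start, prev))
            run_start = k
        prev = k
    if prev - run_start >= min_run:
        phases.append((run_start, prev))

    events: list[ContactEvent] = []
    for p0, p1 in phases:
        if t[p0] < t_start:
            continue
        # last pitch-rate peak before the phase
        b0 = max(0, p0 - int(0.08 * rate))
        peaks, _ = find_peaks(pitch[b0:p0 + 1], prominence=3.0 * low_threshold_dps)
        if len(peaks) == 0:
            continue
        initial = t[b0 + peaks[-1]]
        # last negative vertical-acceleration peak just after the phase
        w0 = p1
        w1 = min(len(t), p1 + int(peak_search_s * rate))
        zpeaks, _ = find_peaks(neg_z[w0:w1], prominence=2.0)
        if len(zpeaks) == 0:
            continue
        terminal = t[w0 + zpeaks[-1]]
        if terminal <= initial:
            continue
        events.append(ContactEvent("ski", side, float(initial), float(terminal)))
    return events


def contact_metrics(
    events: pd.DataFrame | list[ContactEvent],
    cycles: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cycle contact times and their share of the cycle duration.

    Each event is assigned to the cycle containing its initial time;
    ``CT = terminal - initial`` and ``%CT = 100 * CT / cycle duration``.
    Sides are averaged when both are present; cycles without an event carry
    missing markers.  An event outlasting the end of the following cycle is
    an assignment error.
    """
    if not isinstance(events, pd.DataFrame):
        events = events_frame(events)
    starts = cycles["start"].to_numpy(dtype=float)
    ends = cycles["end"].to_numpy(dtype=float)
    n = len(cycles)
    per_side: dict[tuple[str, str], list[list[float]]] = {}
    for kind in ("pole", "ski"):
        for side in ("L", "R"):
            per_side[(kind, side)] = [[] for _ in range(n)]
    for ev in events.itertuples():
        i = int(np.searchsorted(starts, ev.initial, side="right")) - 1
        if i < 0 or i >= n or ev.initial >= ends[i]:
            continue  # outside any cycle
        if i + 1 < n and ev.terminal > ends[i + 1]:
            raise ValueError(
                f"{ev.kind}/{ev.side} event at {ev.initial:.3f} s spans more "
                "than two cycles"
            )
        per_side[(ev.kind, ev.side)][i].append(ev.terminal - ev.initial)

    out = cycles[["start", "end"]].copy()
    durations = ends - starts
    for kind, col in (("pole", "ct_pole"), ("ski", "ct_ski")):
        side_vals = {}
        for side in ("L", "R"):
            vals = np.array(
                [np.mean(v) if v else np.nan for v in per_side[(kind, side)]]
            )
            side_vals[side] = vals
            out[f"{col}_{side}_s"] = vals
        both = np.column_stack([side_vals["L"], side_vals["R"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            ct = np.nanmean(both, axis=1)
        out[f"{col}_s"] = ct
        out[f"pct_{col}"] = 100.0 * ct / durations
    return out
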