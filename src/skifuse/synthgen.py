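"""Synthetic multi-sensor roller-ski session generator with ground truth.

Builds the complete sensor suite of a treadmill skating session — chest,
wrist and ski inertial units (256 Hz), pole axial forces (100 Hz), reflective
markers (200 Hz), heart rate (1 Hz), 10-s mixing-chamber oxygen uptake and
two muscle-oximetry (TSI) streams — together with the ground truth the
analysis stages are scored against: cycle boundaries and sub-technique
labels, pole/ski contact events, the centre-of-mass trajectory and per-cycle
pole/ski power.

The generator is phenomenological, not mechanistic: each sub-technique is a
distinct periodic signature of the upper-body sway, contact events are
injected as the exact signal operators the detectors look for (vibration
burst + reversal peak for poles; pitch-rate peak, low-rotation dwell and
negative vertical-acceleration peak for skis), and physiological series
follow first-order kinetics toward terrain-dependent setpoints.  Everything
is driven by one seeded NumPy generator, so a session is bit-reproducible
from (protocol, intensity, profile, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import ProtocolDefinition, _check_intensity, default_protocol
from .streams_io import SensorStream

__all__ = [
    "SUBTECHNIQUES",
    "SkierProfile",
    "GroundTruth",
    "SyntheticSession",
    "ScheduleWindow",
    "first_order_response",
    "build_subtech_schedule",
    "generate_chest_signal",
    "generate_session",
]

SUBTECHNIQUES = ("G2", "G3", "G4", "other")

IMU_RATE = 256.0
FORCE_RATE = 100.0
MARKER_RATE = 200.0
TSI_RATE = 10.0
GRAVITY = 9.81

#: Nominal cycle rates (cycles/min) per sub-technique and intensity.  Steep
#: uphill G2 cycles are quick, flat-terrain G4 double-poling is slow; HI adds
#: roughly 10 cpm across the board.
CYCLE_RATE_CPM: dict[tuple[str, str], float] = {
    ("G2", "LI"): 55.0,
    ("G2", "HI"): 65.0,
    ("G3", "LI"): 50.0,
    ("G3", "HI"): 60.0,
    ("G4", "LI"): 42.0,
    ("G4", "HI"): 50.0,
    ("other", "LI"): 42.0,
    ("other", "HI"): 46.0,
}

#: Terrain mapping of sub-techniques: moderate uphill -> G3, flat -> G4,
#: steep uphill -> G2 (with a configurable G3 fraction at HI), downhill -> other.
SEGMENT_SUBTECH = {1: "G3", 2: "G4", 3: "G2", 4: "other"}

# Physiological setpoints, in % of individual max (HR, VO2) or raw TSI %.
HR_SETPOINT_PCT = {"LI": {1: 76.0, 2: 73.0, 3: 85.0, 4: 62.0},
                   "HI": {1: 90.0, 2: 86.0, 3: 92.0, 4: 78.0}}
VO2_SETPOINT_PCT = {"LI": {1: 60.0, 2: 55.0, 3: 75.0, 4: 35.0},
                    "HI": {1: 82.0, 2: 76.0, 3: 96.0, 4: 52.0}}
TSI_LEG_SETPOINT = {"LI": {1: 64.0, 2: 66.0, 3: 58.0, 4: 72.0},
                    "HI": {1: 58.0, 2: 62.0, 3: 48.0, 4: 66.0}}
TSI_ARM_SETPOINT = {"LI": {1: 54.0, 2: 56.0, 3: 44.0, 4: 60.0},
                    "HI": {1: 48.0, 2: 52.0, 3: 38.0, 4: 58.0}}
HR_REST_PCT = 45.0
VO2_REST_PCT = 15.0

#: Contact durations as fractions of the cycle period.  Poling is always
#: shorter than ski contact, and both shorten at HI.
CT_POLE_FRAC = {("G2", "LI"): 0.40, ("G3", "LI"): 0.36, ("G4", "LI"): 0.32,
                ("G2", "HI"): 0.36, ("G3", "HI"): 0.32, ("G4", "HI"): 0.28}
CT_SKI_FRAC = {("G2", "LI"): 0.66, ("G3", "LI"): 0.64, ("G4", "LI"): 0.62,
               ("G2", "HI"): 0.59, ("G3", "HI"): 0.57, ("G4", "HI"): 0.55}
POLE_PLANT_PHASE = 0.10   # pole initial contact, fraction of cycle
SKI_PLANT_PHASE_L = 0.04  # left ski initial contact
SKI_PLANT_PHASE_R = 0.54  # right ski, half a cycle later

#: Target pole share of the cycle work rate (% of P_cycle) per segment at
#: lap 1, and the total shift toward ski power from lap 1 to the last lap.
PCT_P_POLE_BASE = {1: 58.0, 2: 60.0, 3: 48.0}
PCT_P_POLE_SHIFT = 7.0
POLE_LEFT_SHARE = 0.48  # left pole share of total pole power

#: Chest-sway signature per sub-technique: amplitude (m/s^2) of the
#: mediolateral fundamental, relative 2nd-harmonic and half-frequency
#: content, and anteroposterior / vertical amplitudes.
_WAVE = {
    "G2": dict(amp=3.0, harm2=0.0, half=0.35, ap=0.7, vert=0.3),
    "G3": dict(amp=2.8, harm2=0.0, half=0.0, ap=0.45, vert=0.5),
    "G4": dict(amp=3.2, harm2=0.22, half=0.0, ap=1.1, vert=0.6),
    "other": dict(amp=0.75, harm2=0.0, half=0.0, ap=0.15, vert=0.1),
}

DEFAULT_NOISE = {
    "chest_accel": 0.15,   # m/s^2 per axis
    "chest_gyro": 1.5,     # deg/s
    "wrist_accel": 0.25,
    "wrist_gyro": 2.0,
    "ski_accel": 0.25,
    "ski_gyro": 3.0,
    "pole_force": 1.5,     # N
    "marker": 0.002,       # m
    "hr": 0.8,             # beats/min
    "vo2": 0.8,            # mL/kg/min
    "tsi": 0.6,            # TSI %-points
}

ALL_STREAMS = ("chest", "wrist_L", "wrist_R", "ski_L", "ski_R",
               "pole_L", "pole_R", "markers", "hr", "vo2",
               "tsi_arm", "tsi_leg")


class ScheduleError(ValueError):
    """Raised for inconsistent sub-technique schedules."""


@dataclass
class SkierProfile:
    """Physiological and anthropometric parameters of one synthetic skier.

    Defaults follow the cohort means of elite male skaters (body mass
    ~80 kg, VO2max ~70.6 mL/min/kg, HRmax ~192 bpm).  ``hr_tau`` /
    ``vo2_tau`` are first-order time constants in seconds;
    ``hr_drift_rate`` is the slow upward cardiovascular drift at HI in
    %-points of HRmax per minute.
    """

    body_mass: float = 80.1
    hr_max: float = 192.0
    vo2max: float = 70.6
    hr_tau: float = 25.0
    vo2_tau: float = 30.0
    hr_drift_rate: float = 0.35
    tsi_baseline_arm: float = 62.0
    tsi_baseline_leg: float = 70.0
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self) -> None:
        if not 150.0 <= self.hr_max <= 220.0:
            raise ValueError(f"hr_max {self.hr_max} outside [150, 220]")
        if self.hr_tau <= 0 or self.vo2_tau <= 0:
            raise ValueError("time constants must be > 0")
        for name in ("tsi_baseline_arm", "tsi_baseline_leg"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} {v} outside (0, 100)")
        merged = dict(DEFAULT_NOISE)
        merged.update(self.noise)
        self.noise = merged


@dataclass(frozen=True)
class ScheduleWindow:
    """A contiguous stretch of one sub-technique at a fixed cycle rate."""

    start: float
    end: float
    label: str
    cycle_rate: float  # cycles/min, quantized so cycles tile the window
    lap: int
    segment: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_cycles(self) -> int:
        return int(round(self.duration * self.cycle_rate / 60.0))


@dataclass
class GroundTruth:
    """Everything the downstream detectors are scored against."""

    cycles: pd.DataFrame       # start, end, label, cycle_rate, lap, segment
    contacts: pd.DataFrame     # kind, side, initial, terminal
    power: pd.DataFrame        # per poling cycle: p_cycle, p_pole, sides, p_ski
    schedule: pd.DataFrame     # start, end, label, cycle_rate, lap, segment
    sync_jumps: np.ndarray     # master-clock times of the three IMU sync spikes
    hr_pct: np.ndarray         # per-second %HRmax (noise-free kinetics)
    vo2_pct: np.ndarray        # per-second %VO2max
    tsi_leg: np.ndarray        # per-second TSI %
    tsi_arm: np.ndarray
    com: pd.DataFrame | None   # 200 Hz time_s, x, y, z, vx, vy, vz (noise-free)
    stream_offsets: dict[str, float]


@dataclass
class SyntheticSession:
    """A full synthetic recording: sensor streams + ground truth."""

    streams: dict[str, SensorStream]
    truth: GroundTruth
    profile: SkierProfile
    protocol: ProtocolDefinition
    intensity: str
    seed: int


# ---------------------------------------------------------------------------
# physiological kinetics
# ---------------------------------------------------------------------------

def first_order_response(
    target: np.ndarray,
    tau: float,
    drift: float = 0.0,
    y0: float | None = None,
) -> np.ndarray:
    """First-order relaxation of a per-second series toward a setpoint.

    ``y[t+1] = y[t] + (target[t] - y[t]) * (1 - exp(-1/tau)) + drift/60``,
    clamped to [0, 100].  ``tau`` is the time constant in seconds, ``drift``
    a constant inflow in %-points per minute (balanced by the relaxation, it
    converges to a steady offset of ``drift * tau / 60``).

    ``y0`` defaults to ``target[0]``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    target = np.asarray(target, dtype=float)
    alpha = 1.0 - math.exp(-1.0 / tau)
    y = np.empty(len(target))
    y[0] = float(target[0]) if y0 is None else float(y0)
    for t in range(len(target) - 1):
        y[t + 1] = y[t] + (target[t] - y[t]) * alpha + drift / 60.0
    np.clip(y, 0.0, 100.0, out=y)
    return y


# ---------------------------------------------------------------------------
# sub-technique schedule
# ---------------------------------------------------------------------------

def _quantized_rate(duration: float, cpm: float) -> float:
    """Adjust a cycle rate so an integer number of cycles tiles the window."""
    n = max(1, int(round(duration * cpm / 60.0)))
    return 60.0 * n / duration


def build_subtech_schedule(
    protocol: ProtocolDefinition,
    intensity: str,
    g3_fraction_steep_hi: float = 0.35,
    transition_jitter_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ScheduleWindow]:
    """Terrain-driven sub-technique schedule with quantized cycle rates.

    Moderate uphill maps to G3, flat to G4, steep uphill to G2 (at HI the
    first ``g3_fraction_steep_hi`` of the steep segment is skied in G3) and
    the downhill to "other" (tuck).  Transitions sit at segment boundaries,
    optionally jittered by up to ``transition_jitter_s``.  Within each
    window the cycle rate is adjusted by at most about one percent so an
    integer number of cycles tiles the window exactly; every generated cycle
    therefore carries a single label.
    """
    _check_intensity(intensity)
    rng = rng or np.random.default_rng(0)
    pieces: list[tuple[float, float, str]] = []
    for w in protocol.windows():
        label = SEGMENT_SUBTECH.get(w.segment, "other")
        if label == "G2" and intensity == "HI" and g3_fraction_steep_hi > 0:
            split = w.start + g3_fraction_steep_hi * (w.end - w.start)
            pieces.append((w.start, split, "G3"))
            pieces.append((split, w.end, "G2"))
        else:
            pieces.append((w.start, w.end, label))
    if transition_jitter_s > 0:
        starts = [p[0] for p in pieces]
        for i in range(1, len(pieces)):
            starts[i] += float(rng.uniform(-transition_jitter_s, transition_jitter_s))
        new = []
        for i, (s, e, lab) in enumerate(pieces):
            s2 = starts[i]
            e2 = starts[i + 1] if i + 1 < len(pieces) else e
            if e2 <= s2:
                raise ScheduleError("jitter produced an empty or inverted window")
            new.append((s2, e2, lab))
        pieces = new
    windows = []
    for s, e, lab in pieces:
        lap, segment = protocol.lap_segment_at(min(s + 1e-6, protocol.total_duration - 1e-6))
        windows.append(
            ScheduleWindow(
                start=s, end=e, label=lab,
                cycle_rate=_quantized_rate(e - s, CYCLE_RATE_CPM[(lab, intensity)]),
                lap=int(lap), segment=int(segment),
            )
        )
    for a, b in zip(windows, windows[1:]):
        if b.start < a.end - 1e-9:
            raise ScheduleError(f"overlapping schedule windows at {b.start:.3f} s")
    return windows


def _schedule_frame(windows: Sequence[ScheduleWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "label": [w.label for w in windows],
            "cycle_rate": [w.cycle_rate for w in windows],
            "lap": [w.lap for w in windows],
            "segment": [w.segment for w in windows],
        }
    )


def _truth_cycles(windows: Sequence[ScheduleWindow]) -> pd.DataFrame:
    """Per-cycle table implied by the schedule (cycles tile each window)."""
    rows = []
    for w in windows:
        period = 60.0 / w.cycle_rate
        for k in range(w.n_cycles):
            rows.append(
                (w.start + k * period, w.start + (k + 1) * period,
                 w.label, w.cycle_rate, w.lap, w.segment)
            )
    return pd.DataFrame(
        rows, columns=["start", "end", "label", "cycle_rate", "lap", "segment"]
    )


def _phase(t: np.ndarray, windows: Sequence[ScheduleWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Cycle phase (cycles since window start) and window index per sample.

    Samples outside every window (e.g. the calibration prefix) get phase 0
    and window index -1.
    """
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.where((idx >= 0) & (t < ends[np.clip(idx, 0, len(windows) - 1)]), idx, -1)
    phase = np.zeros_like(t, dtype=float)
    for i, w in enumerate(windows):
        m = idx == i
        if np.any(m):
            phase[m] = (t[m] - w.start) * w.cycle_rate / 60.0
    return phase, idx


# ---------------------------------------------------------------------------
# chest signal
# ---------------------------------------------------------------------------

def generate_chest_signal(
    windows: Sequence[ScheduleWindow],
    rng: np.random.Generator,
    rate: float = IMU_RATE,
    noise_sd: float = DEFAULT_NOISE["chest_accel"],
    gyro_noise_sd: float = DEFAULT_NOISE["chest_gyro"],
    t_start: float = 0.0,
    t_end: float | None = None,
    sync_jumps: Sequence[float] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """256 Hz six-channel chest IMU signal plus the truth cycle table.

    The mediolateral channel (``acc_y``) is a periodic sway at the scheduled
    cycle rate whose minima ("left-position") mark cycle starts.  Each
    sub-technique has a distinct signature: G2 carries a half-frequency
    component (every-other-cycle asymmetry), G3 is a clean fundamental, G4
    adds a second harmonic with the largest poling (anteroposterior)
    amplitude, and "other" is low-amplitude sway.

    Returns ``(frame, cycles)`` where ``frame`` has columns ``time_s`` and
    ``acc_x/y/z``, ``gyro_x/y/z`` and ``cycles`` is the truth cycle table.
    """
    for a, b in zip(windows, windows[1:]):
        if b.start < a.end - 1e-9:
            raise ScheduleError("overlapping schedule windows")
    if t_end is None:
        t_end = windows[-1].end
    n = int(round((t_end - t_start) * rate))
    t = t_start + np.arange(n) / rate
    phase, widx = _phase(t, windows)
    theta = 2.0 * np.pi * phase

    acc_x = np.zeros(n)
    acc_y = np.zeros(n)
    acc_z = np.zeros(n)
    gyro_x = np.zeros(n)
    gyro_y = np.zeros(n)
    gyro_z = np.zeros(n)
    for i, w in enumerate(windows):
        m = widx == i
        if not np.any(m):
            continue
        p = _WAVE[w.label]
        th = theta[m]
        amp = p["amp"]
        acc_y[m] = -amp * (
            np.cos(th) + p["harm2"] * np.cos(2 * th) + p["half"] * np.cos(th / 2.0)
        )
        acc_x[m] = p["ap"] * amp * np.sin(th)
        acc_z[m] = p["vert"] * amp * np.sin(2 * th)
        gyro_z[m] = 40.0 * np.sin(th)
        gyro_x[m] = 15.0 * np.cos(th)
        gyro_y[m] = 10.0 * np.sin(2 * th)
    acc_z += GRAVITY
    for tj in sync_jumps:
        acc_z += 30.0 * np.exp(-0.5 * ((t - tj) / 0.01) ** 2)

    acc_x += rng.normal(0.0, noise_sd, n)
    acc_y += rng.normal(0.0, noise_sd, n)
    acc_z += rng.normal(0.0, noise_sd, n)
    gyro_x += rng.normal(0.0, gyro_noise_sd, n)
    gyro_y += rng.normal(0.0, gyro_noise_sd, n)
    gyro_z += rng.normal(0.0, gyro_noise_sd, n)

    frame = pd.DataFrame(
        {
            "time_s": t,
            "acc_x": acc_x,
            "acc_y": acc_y,
            "acc_z": acc_z,
            "gyro_x": gyro_x,
            "gyro_y": gyro_y,
            "gyro_z": gyro_z,
        }
    )
    return frame, _truth_cycles(windows)


# ---------------------------------------------------------------------------
# contact events and limb streams
# ---------------------------------------------------------------------------

def _truth_contacts(cycles: pd.DataFrame, intensity: str) -> pd.DataFrame:
    """Pole and ski contact events implied by the cycle table."""
    rows = []
    for c in cycles.itertuples():
        if c.label == "other":
            continue
        period = c.end - c.start
        ct_pole = CT_POLE_FRAC[(c.label, intensity)] * period
        t_pole = c.start + POLE_PLANT_PHASE * period
        for side in ("L", "R"):
            rows.append(("pole", side, t_pole, t_pole + ct_pole))
        ct_ski = CT_SKI_FRAC[(c.label, intensity)] * period
        for side, ph in (("L", SKI_PLANT_PHASE_L), ("R", SKI_PLANT_PHASE_R)):
            t_ski = c.start + ph * period
            rows.append(("ski", side, t_ski, t_ski + ct_ski))
    out = pd.DataFrame(rows, columns=["kind", "side", "initial", "terminal"])
    return out.sort_values(["kind", "side", "initial"]).reset_index(drop=True)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _gauss(t: np.ndarray, t0: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def _generate_wrist(
    t: np.ndarray,
    phase: np.ndarray,
    widx: np.ndarray,
    windows: Sequence[ScheduleWindow],
    events: pd.DataFrame,
    intensity: str,
    rng: np.random.Generator,
    noise_acc: float,
    noise_gyro: float,
    sync_jumps: Sequence[float],
) -> pd.DataFrame:
    """Wrist IMU: arm swing + vibration burst at pole plant, reversal peak
    and angular-speed minimum at pole lift-off."""
    n = len(t)
    th = 2.0 * np.pi * phase
    acc_x = 1.5 * np.sin(th)
    acc_y = 0.3 * np.cos(th)
    acc_z = GRAVITY + 0.8 * np.cos(th)
    gyro_x = np.zeros(n)
    gyro_z = np.zeros(n)
    # Angular speed dips to zero exactly at pole lift-off once per cycle.
    gyro_y = 20.0 * np.sin(th)
    for i, w in enumerate(windows):
        if w.label == "other":
            continue
        m = widx == i
        if not np.any(m):
            continue
        term_phase = POLE_PLANT_PHASE + CT_POLE_FRAC[(w.label, intensity)]
        gyro_y[m] = 150.0 * np.sin(np.pi * (phase[m] - term_phase))

    rate = 1.0 / (t[1] - t[0])
    for ev in events.itertuples():
        i0 = int(np.searchsorted(t, ev.initial - 0.02))
        i1 = int(np.searchsorted(t, ev.initial + 0.12))
        tau = t[i0:i1] - ev.initial
        burst = 6.0 * np.exp(-np.clip(tau, 0.0, None) / 0.025) * np.cos(2 * np.pi * 45.0 * tau)
        burst[tau < 0] = 0.0
        acc_x[i0:i1] += burst
        j0 = int(np.searchsorted(t, ev.terminal - 0.05))
        j1 = int(np.searchsorted(t, ev.terminal + 0.05))
        acc_x[j0:j1] += 12.0 * _gauss(t[j0:j1], ev.terminal, 0.012)
    for tj in sync_jumps:
        acc_z += 30.0 * _gauss(t, tj, 0.01)

    acc_x += rng.normal(0.0, noise_acc, n)
    acc_y += rng.normal(0.0, noise_acc, n)
    acc_z += rng.normal(0.0, noise_acc, n)
    gyro_x += rng.normal(0.0, noise_gyro, n)
    gyro_y += rng.normal(0.0, noise_gyro, n)
    gyro_z += rng.normal(0.0, noise_gyro, n)
    return pd.DataFrame(
        {"time_s": t, "acc_x": acc_x, "acc_y": acc_y, "acc_z": acc_z,
         "gyro_x": gyro_x, "gyro_y": gyro_y, "gyro_z": gyro_z}
    )


def _generate_ski(
    t: np.ndarray,
    events: pd.DataFrame,
    rng: np.random.Generator,
    noise_acc: float,
    noise_gyro: float,
    sync_jumps: Sequence[float],
) -> pd.DataFrame:
    """Ski IMU: swing rotation that stops during ground contact, a pitch-rate
    peak at initial contact and a negative vertical-acceleration peak at
    terminal contact."""
    n = len(t)
    env = np.ones(n)
    pitch_bumps = np.zeros(n)
    z_spikes = np.zeros(n)
    for ev in events.itertuples():
        # swing stops shortly before the plant and resumes around lift-off
        d0 = int(np.searchsorted(t, ev.initial - 0.08))
        d1 = int(np.searchsorted(t, ev.initial - 0.03))
        if d1 > d0:
            env[d0:d1] = np.minimum(env[d0:d1], 1.0 - _smoothstep(
                (t[d0:d1] - (ev.initial - 0.08)) / 0.05))
        u0 = int(np.searchsorted(t, ev.terminal - 0.03))
        u1 = int(np.searchsorted(t, ev.terminal + 0.02))
        env[d1:u0] = 0.0
        if u1 > u0:
            env[u0:u1] = np.maximum(env[u0:u1], _smoothstep(
                (t[u0:u1] - (ev.terminal - 0.03)) / 0.05))
        b0 = int(np.searchsorted(t, ev.initial - 0.04))
        b1 = int(np.searchsorted(t, ev.initial + 0.04))
        pitch_bumps[b0:b1] += 260.0 * _gauss(t[b0:b1], ev.initial, 0.008)
        s0 = int(np.searchsorted(t, ev.terminal - 0.04))
        s1 = int(np.searchsorted(t, ev.terminal + 0.04))
        z_spikes[s0:s1] += 9.0 * _gauss(t[s0:s1], ev.terminal, 0.008)

    swing = 200.0 * (0.35 + 0.65 * np.abs(np.sin(2 * np.pi * 2.0 * t)))
    gyro_y = swing * env + pitch_bumps
    acc_z = GRAVITY + 0.5 * np.sin(2 * np.pi * 1.0 * t) - z_spikes
    acc_x = 0.8 * np.sin(2 * np.pi * 1.0 * t)
    acc_y = 0.3 * np.cos(2 * np.pi * 1.0 * t)
    for tj in sync_jumps:
        acc_z += 30.0 * _gauss(t, tj, 0.01)

    out = pd.DataFrame(
        {
            "time_s": t,
            "acc_x": acc_x + rng.normal(0.0, noise_acc, n),
            "acc_y": acc_y + rng.normal(0.0, noise_acc, n),
            "acc_z": acc_z + rng.normal(0.0, noise_acc, n),
            "gyro_x": rng.normal(0.0, noise_gyro, n),
            "gyro_y": gyro_y + rng.normal(0.0, noise_gyro, n),
            "gyro_z": rng.normal(0.0, noise_gyro, n),
        }
    )
    return out


# ---------------------------------------------------------------------------
# centre of mass, markers, pole forces and power truth
# ---------------------------------------------------------------------------

#: Unit pole directions (from tip to grip; x forward, y sideways, z up).
def _pole_direction(side: str) -> np.ndarray:
    u = np.array([0.40, -0.07 if side == "L" else 0.07, 0.91])
    return u / np.linalg.norm(u)


POLE_LENGTH = 1.45
_POLE_GRIP_OFFSET = {"L": np.array([0.25, -0.30, 0.45]),
                     "R": np.array([0.25, 0.30, 0.45])}

#: Reduced body-segment table used for the marker cloud: (mass fraction,
#: CoM position fraction from proximal to distal marker).
BODY_SEGMENTS = (
    ("trunk", 0.50, 0.50),
    ("legs", 0.35, 0.45),
    ("arms", 0.15, 0.45),
)


def _com_velocity_components(
    t: np.ndarray, belt_ms: np.ndarray, phase: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free CoM velocity: forward speed oscillating about the belt
    speed plus lateral sway and vertical bob locked to the cycle."""
    th = 2.0 * np.pi * phase
    vx = belt_ms + 0.30 * np.sin(th)
    vy = 0.25 * np.cos(th)
    vz = 0.12 * np.sin(2 * th)
    return vx, vy, vz


def _segment_marker_offsets() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Constant proximal/distal marker offsets whose mass-weighted combination
    is exactly zero, so the weighted marker sum reproduces the CoM."""
    offs = {
        "trunk": (np.array([0.0, 0.0, 0.35]), np.array([0.0, 0.0, -0.15])),
        "legs": (np.array([0.0, 0.0, -0.50]), np.array([0.0, 0.0, -1.00])),
    }
    total = np.zeros(3)
    for name, w, f in BODY_SEGMENTS:
        if name == "arms":
            continue
        p, d = offs[name]
        total += w * ((1 - f) * p + f * d)
    # solve the arms' distal offset so the weighted sum cancels exactly
    w_arms, f_arms = 0.15, 0.45
    p_arms = np.array([0.0, 0.0, 1.20])
    d_arms = (-total / w_arms - (1 - f_arms) * p_arms) / f_arms
    offs["arms"] = (p_arms, d_arms)
    return offs


def _truth_power(
    cycles: pd.DataFrame,
    protocol: ProtocolDefinition,
    intensity: str,
    profile: SkierProfile,
    windows: Sequence[ScheduleWindow],
    mu: float = 0.016,
) -> pd.DataFrame:
    """Per-cycle work rate and target pole power for poling cycles in the
    uphill/flat segments (downhill excluded: the skier holds a rope)."""
    n_laps = protocol.laps
    rows = []
    for idx, c in enumerate(cycles.itertuples()):
        if c.label == "other" or c.segment not in PCT_P_POLE_BASE:
            continue
        mid = 0.5 * (c.start + c.end)
        v = float(protocol.speed_kmh_at(mid, intensity)) / 3.6
        grade = float(protocol.incline_at(mid))
        theta = math.atan(grade)
        p_cycle = profile.body_mass * GRAVITY * v * (math.sin(theta) + mu * math.cos(theta))
        frac = (c.lap - 1) / max(1, n_laps - 1)
        pct_pole = PCT_P_POLE_BASE[c.segment] - PCT_P_POLE_SHIFT * frac
        p_pole = pct_pole / 100.0 * p_cycle
        rows.append(
            (idx, c.start, c.end, c.label, c.lap, c.segment, p_cycle,
             p_pole, POLE_LEFT_SHARE * p_pole, (1 - POLE_LEFT_SHARE) * p_pole,
             p_cycle - p_pole, pct_pole)
        )
    return pd.DataFrame(
        rows,
        columns=["cycle_index", "start", "end", "label", "lap", "segment",
                 "p_cycle", "p_pole", "p_pole_left", "p_pole_right",
                 "p_ski", "pct_p_pole"],
    )


def _generate_pole_forces_and_markers(
    cycles: pd.DataFrame,
    power_truth: pd.DataFrame,
    windows: Sequence[ScheduleWindow],
    protocol: ProtocolDefinition,
    intensity: str,
    profile: SkierProfile,
    rng: np.random.Generator,
    want_forces: bool,
    want_markers: bool,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame | None, pd.DataFrame | None]:
    """Pole force streams (100 Hz), marker cloud (200 Hz) and CoM truth.

    Pole force is a smooth ``sin^2`` bump inside each truth poling phase,
    scaled per cycle so that the cycle-average of force x CoM velocity hits
    the target pole power recorded in the power truth table.
    """
    total = protocol.total_duration
    tm = np.arange(int(round(total * MARKER_RATE))) / MARKER_RATE
    phase_m, _ = _phase(tm, windows)
    belt_m = protocol.speed_kmh_at(np.minimum(tm, total - 1e-9), intensity) / 3.6
    vx, vy, vz = _com_velocity_components(tm, belt_m, phase_m)
    x = np.concatenate([[0.0], np.cumsum(vx[:-1] + vx[1:]) / (2 * MARKER_RATE)])
    y = np.concatenate([[0.0], np.cumsum(vy[:-1] + vy[1:]) / (2 * MARKER_RATE)])
    z = 1.10 + np.concatenate([[0.0], np.cumsum(vz[:-1] + vz[1:]) / (2 * MARKER_RATE)])
    com = pd.DataFrame({"time_s": tm, "x": x, "y": y, "z": z,
                        "vx": vx, "vy": vy, "vz": vz})

    forces: dict[str, pd.DataFrame] = {}
    if want_forces:
        tf = np.arange(int(round(total * FORCE_RATE))) / FORCE_RATE
        force = {"L": np.zeros(len(tf)), "R": np.zeros(len(tf))}
        for row in power_truth.itertuples():
            c = cycles.iloc[int(row.cycle_index)]
            period = c["end"] - c["start"]
            ct = CT_POLE_FRAC[(c["label"], intensity)] * period
            t0 = c["start"] + POLE_PLANT_PHASE * period
            for side, p_target in (("L", row.p_pole_left), ("R", row.p_pole_right)):
                u = _pole_direction(side)
                i0 = int(np.searchsorted(tf, t0))
                i1 = int(np.searchsorted(tf, t0 + ct))
                if i1 <= i0:
                    continue
                tt = tf[i0:i1]
                shape = np.sin(np.pi * (tt - t0) / ct) ** 2
                uv = (u[0] * np.interp(tt, tm, vx)
                      + u[1] * np.interp(tt, tm, vy)
                      + u[2] * np.interp(tt, tm, vz))
                integral = np.sum(shape * uv) / FORCE_RATE
                f_max = p_target * period / integral
                force[side][i0:i1] += f_max * shape
        sd = profile.noise["pole_force"]
        for side in ("L", "R"):
            noisy = force[side] + rng.normal(0.0, sd, len(tf))
            forces[side] = pd.DataFrame(
                {"time_s": tf, "force_n": np.clip(noisy, 0.0, None)}
            )

    markers = None
    if want_markers:
        cols: dict[str, np.ndarray] = {"time_s": tm}
        sd = profile.noise["marker"]
        offs = _segment_marker_offsets()
        compos = np.column_stack([x, y, z])
        for name, _, _ in BODY_SEGMENTS:
            p_off, d_off = offs[name]
            for tag, off in (("prox", p_off), ("dist", d_off)):
                pos = compos + off
                for ax, k in zip("xyz", range(3)):
                    cols[f"{name}_{tag}_{ax}"] = pos[:, k] + rng.normal(0.0, sd, len(tm))
        for side in ("L", "R"):
            u = _pole_direction(side)
            grip = compos + _POLE_GRIP_OFFSET[side]
            tip = grip - POLE_LENGTH * u
            for tag, pos in (("grip", grip), ("tip", tip)):
                for ax, k in zip("xyz", range(3)):
                    cols[f"pole_{side}_{tag}_{ax}"] = (
                        pos[:, k] + rng.normal(0.0, 0.001, len(tm))
                    )
        markers = pd.DataFrame(cols)
    return forces, markers, com


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def generate_session(
    protocol: ProtocolDefinition | None = None,
    intensity: str = "LI",
    profile: SkierProfile | None = None,
    seed: int = 0,
    include: Iterable[str] | None = None,
    calibration_s: float = 10.0,
    g3_fraction_steep_hi: float = 0.35,
    transition_jitter_s: float = 0.0,
    stream_offsets: Mapping[str, float] | None = None,
) -> SyntheticSession:
    """Generate one complete synthetic session.

    Parameters
    ----------
    protocol, intensity, profile, seed
        Study conditions.  The default protocol is the packaged 7 x 180 s
        varying-terrain schedule; the default profile the cohort-mean skier.
    include
        Names of streams to synthesize (subset of ``ALL_STREAMS``); ground
        truth is always complete.  Restricting to e.g. ``{"chest"}`` speeds
        up corpus generation considerably.
    calibration_s
        Length of the pre-session calibration window on the IMU streams;
        three synchronization jumps are injected there.
    stream_offsets
        Optional per-stream clock offsets (seconds) applied to the written
        timestamps; recorded in the truth so alignment can be scored.
    """
    protocol = protocol or default_protocol()
    _check_intensity(intensity)
    profile = profile or SkierProfile()
    include = set(ALL_STREAMS if include is None else include)
    unknown = include - set(ALL_STREAMS)
    if unknown:
        raise ValueError(f"unknown streams requested: {sorted(unknown)}")
    stream_offsets = dict(stream_offsets or {})
    rng = np.random.default_rng(seed)
    total = protocol.total_duration

    windows = build_subtech_schedule(
        protocol, intensity, g3_fraction_steep_hi, transition_jitter_s, rng
    )
    sync_jumps = np.array([-0.8, -0.6, -0.4]) * calibration_s
    cycles = _truth_cycles(windows)
    contacts = _truth_contacts(cycles, intensity)
    power_truth = _truth_power(cycles, protocol, intensity, profile, windows)

    # --- physiological truth (per-second, noise-free kinetics) ---
    sec = np.arange(int(total))
    lap_sec, seg_sec = protocol.lap_segment_at(sec.astype(float))
    hr_target = np.array([HR_SETPOINT_PCT[intensity][s] for s in seg_sec])
    if intensity == "HI" and profile.hr_drift_rate:
        hr_target = hr_target + profile.hr_drift_rate * sec / 60.0
    vo2_target = np.array([VO2_SETPOINT_PCT[intensity][s] for s in seg_sec])
    tsi_leg_t = np.array([TSI_LEG_SETPOINT[intensity][s] for s in seg_sec])
    tsi_arm_t = np.array([TSI_ARM_SETPOINT[intensity][s] for s in seg_sec])
    hr_pct = first_order_response(hr_target, profile.hr_tau, y0=HR_REST_PCT)
    vo2_pct = first_order_response(vo2_target, profile.vo2_tau, y0=VO2_REST_PCT)
    tsi_leg = first_order_response(tsi_leg_t, 10.0, y0=profile.tsi_baseline_leg)
    tsi_arm = first_order_response(tsi_arm_t, 10.0, y0=profile.tsi_baseline_arm)

    streams: dict[str, SensorStream] = {}

    def _offset(name: str) -> float:
        return float(stream_offsets.get(name, 0.0))

    # --- chest (cycle truth itself comes from the schedule) ---
    if "chest" in include:
        chest_frame, _ = generate_chest_signal(
            windows, rng,
            noise_sd=profile.noise["chest_accel"],
            gyro_noise_sd=profile.noise["chest_gyro"],
            t_start=-calibration_s, t_end=total, sync_jumps=sync_jumps,
        )
        streams["chest"] = _as_stream(chest_frame, "chest", IMU_RATE, _offset("chest"))

    # --- wrists and skis ---
    if include & {"wrist_L", "wrist_R", "ski_L", "ski_R"}:
        t_imu = -calibration_s + np.arange(int(round((total + calibration_s) * IMU_RATE))) / IMU_RATE
        phase_imu, widx_imu = _phase(t_imu, windows)
        for side in ("L", "R"):
            name = f"wrist_{side}"
            if name in include:
                ev = contacts[(contacts["kind"] == "pole") & (contacts["side"] == side)]
                frame = _generate_wrist(
                    t_imu, phase_imu, widx_imu, windows, ev, intensity, rng,
                    profile.noise["wrist_accel"], profile.noise["wrist_gyro"],
                    sync_jumps,
                )
                streams[name] = _as_stream(frame, name, IMU_RATE, _offset(name))
            name = f"ski_{side}"
            if name in include:
                ev = contacts[(contacts["kind"] == "ski") & (contacts["side"] == side)]
                frame = _generate_ski(
                    t_imu, ev, rng,
                    profile.noise["ski_accel"], profile.noise["ski_gyro"],
                    sync_jumps,
                )
                streams[name] = _as_stream(frame, name, IMU_RATE, _offset(name))

    # --- pole forces, markers, CoM truth ---
    want_forces = bool(include & {"pole_L", "pole_R"})
    want_markers = "markers" in include
    com = None
    if want_forces or want_markers:
        forces, markers, com = _generate_pole_forces_and_markers(
            cycles, power_truth, windows, protocol, intensity, profile, rng,
            want_forces, want_markers,
        )
        for side in ("L", "R"):
            name = f"pole_{side}"
            if name in include and side in forces:
                streams[name] = _as_stream(forces[side], name, FORCE_RATE, _offset(name))
        if want_markers and markers is not None:
            streams["markers"] = _as_stream(markers, "markers", MARKER_RATE, _offset("markers"))

    # --- physiological streams ---
    if "hr" in include:
        bpm = hr_pct * profile.hr_max / 100.0 + rng.normal(0.0, profile.noise["hr"], len(sec))
        frame = pd.DataFrame({"time_s": sec.astype(float), "bpm": bpm})
        streams["hr"] = _as_stream(frame, "hr", 1.0, _offset("hr"))
    if "vo2" in include:
        blocks = np.arange(0, int(total), 10)
        vals = np.array([
            vo2_pct[b:b + 10].mean() * profile.vo2max / 100.0 for b in blocks
        ]) + rng.normal(0.0, profile.noise["vo2"], len(blocks))
        frame = pd.DataFrame({"time_s": blocks.astype(float), "ml_per_kg_min": vals})
        streams["vo2"] = _as_stream(frame, "vo2", 0.1, _offset("vo2"))
    for name, series in (("tsi_arm", tsi_arm), ("tsi_leg", tsi_leg)):
        if name in include:
            tt = np.arange(int(total * TSI_RATE)) / TSI_RATE
            vals = np.interp(tt, sec.astype(float), series)
            vals = np.clip(vals + rng.normal(0.0, profile.noise["tsi"], len(tt)), 0.5, 99.5)
            frame = pd.DataFrame({"time_s": tt, "tsi_pct": vals})
            streams[name] = _as_stream(frame, name, TSI_RATE, _offset(name))

    truth = GroundTruth(
        cycles=cycles,
        contacts=contacts,
        power=power_truth,
        schedule=_schedule_frame(windows),
        sync_jumps=sync_jumps,
        hr_pct=hr_pct,
        vo2_pct=vo2_pct,
        tsi_leg=tsi_leg,
        tsi_arm=tsi_arm,
        com=com,
        stream_offsets=stream_offsets,
    )
    return SyntheticSession(
        streams=streams, truth=truth, profile=profile,
        protocol=protocol, intensity=intensity, seed=seed,
    )


def _as_stream(frame: pd.DataFrame, placement: str, rate: float, offset: float) -> SensorStream:
    if offset:
        frame = frame.copy()
        frame["time_s"] = frame["time_s"] + offset
    return SensorStream(placement=placement, rate=rate, t0=-offset, data=frame)
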