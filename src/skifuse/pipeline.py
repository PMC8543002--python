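"""End-to-end session analysis: streams -> cycles -> contacts -> power ->
master timeline.

This is the conductor over the per-stage modules: it detects and classifies
cycles from the chest stream, derives contact times from wrists and skis,
partitions pole/ski power on the laps the motion-capture system recorded
(the odd laps) for the uphill/flat segments, and merges everything with the
physiological streams into the 1 Hz master timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import contacts as _contacts
from . import cycles as _cycles
from . import power as _power
from .protocol import ProtocolDefinition
from .streams_io import build_master_timeline
from .synthgen import SyntheticSession

__all__ = [
    "SessionAnalysis",
    "speed_series_ms",
    "analyze_session",
    "truth_labels_for_cycles",
    "session_feature_corpus",
    "train_session_model",
]

POWER_SEGMENTS = (1, 2, 3)  # downhill excluded: the skier holds a rope


@dataclass
class SessionAnalysis:
    """Analyzed session: per-cycle table, contact events and master timeline."""

    cycle_table: pd.DataFrame
    events: pd.DataFrame
    master: pd.DataFrame


def speed_series_ms(protocol: ProtocolDefinition, intensity: str) -> np.ndarray:
    """Per-second treadmill belt speed (m/s), sampled at second midpoints."""
    sec = np.arange(int(protocol.total_duration)) + 0.5
    return protocol.speed_kmh_at(sec, intensity) / 3.6


def truth_labels_for_cycles(
    cycle_table: pd.DataFrame, truth_cycles: pd.DataFrame
) -> np.ndarray:
    """Ground-truth label per detected cycle (by cycle midpoint containment);
    cycles outside every truth cycle get ``None``."""
    mid = 0.5 * (cycle_table["start"].to_numpy() + cycle_table["end"].to_numpy())
    starts = truth_cycles["start"].to_numpy(dtype=float)
    ends = truth_cycles["end"].to_numpy(dtype=float)
    labels = truth_cycles["label"].to_numpy()
    idx = np.searchsorted(starts, mid, side="right") - 1
    ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(ends) - 1)])
    out = np.full(len(mid), None, dtype=object)
    out[ok] = labels[idx[ok]]
    return out


def _detect_and_describe_cycles(
    session: SyntheticSession,
) -> tuple[pd.DataFrame, np.ndarray]:
    chest = session.streams["chest"]
    protocol = session.protocol
    boundaries = _cycles.detect_cycles(chest, t_start=0.0, t_end=protocol.total_duration)
    if len(boundaries) < 2:
        raise ValueError("fewer than two cycle boundaries detected")
    speed = speed_series_ms(protocol, session.intensity)
    table = _cycles.cycle_kinematics(boundaries, speed)
    features = _cycles.features_for_cycles(chest, boundaries)
    mid = 0.5 * (table["start"].to_numpy() + table["end"].to_numpy())
    lap, segment = protocol.lap_segment_at(mid)
    table["lap"] = lap
    table["segment"] = segment
    return table, features


def _attach_contacts(session: SyntheticSession, table: pd.DataFrame) -> pd.DataFrame:
    events: list[_contacts.ContactEvent] = []
    for side in ("L", "R"):
        w = session.streams.get(f"wrist_{side}")
        if w is not None:
            events += _contacts.detect_pole_contacts(w, side=side, t_start=0.0)
        s = session.streams.get(f"ski_{side}")
        if s is not None:
            events += _contacts.detect_ski_contacts(s, side=side, t_start=0.0)
    ev_frame = _contacts.events_frame(events)
    if len(ev_frame):
        metrics = _contacts.contact_metrics(ev_frame, table)
        for col in ("ct_pole_s", "ct_ski_s", "pct_ct_pole", "pct_ct_ski"):
            table[col] = metrics[col].to_numpy()
    return ev_frame


def _attach_power(
    session: SyntheticSession,
    table: pd.DataFrame,
    odd_laps_only: bool = True,
    lowpass_hz: float | None = 10.0,
) -> None:
    markers = session.streams.get("markers")
    pole_l = session.streams.get("pole_L")
    pole_r = session.streams.get("pole_R")
    if markers is None or pole_l is None or pole_r is None:
        return
    mdf = markers.data
    tm = markers.master_time
    rate = markers.rate
    seg_table = _power.default_segment_table()
    com = _power.com_from_markers(mdf, seg_table)
    vel = _power.com_velocity(com, rate, lowpass_hz=lowpass_hz)
    inst: dict[str, np.ndarray] = {}
    for side, stream in (("L", pole_l), ("R", pole_r)):
        force = np.interp(tm, stream.master_time, stream.channel("force_n"))
        direction = _power.pole_direction_from_markers(mdf, side)
        inst[side] = _power.pole_power(force, direction, vel)

    protocol = session.protocol
    mass = session.profile.body_mass
    cols = {c: np.full(len(table), np.nan) for c in (
        "p_cycle_w", "p_pole_w", "p_pole_left_w", "p_pole_right_w", "p_ski_w",
        "pct_p_pole", "pct_p_ski", "pct_p_pole_left", "pct_p_pole_right")}
    for i, c in enumerate(table.itertuples()):
        if c.label not in ("G2", "G3", "G4"):
            continue
        if c.segment not in POWER_SEGMENTS:
            continue
        if odd_laps_only and c.lap % 2 == 0:
            continue
        i0 = int(np.searchsorted(tm, c.start))
        i1 = int(np.searchsorted(tm, c.end))
        if i1 - i0 < 4:
            continue
        p_left = float(np.mean(inst["L"][i0:i1]))
        p_right = float(np.mean(inst["R"][i0:i1]))
        mid = 0.5 * (c.start + c.end)
        v = float(protocol.speed_kmh_at(mid, session.intensity)) / 3.6
        grade = float(protocol.incline_at(mid))
        p_cycle = _power.cycle_work_rate(mass, v, grade)
        rec = _power.partition_power(p_cycle, p_left + p_right, p_left, p_right)
        cols["p_cycle_w"][i] = rec.p_cycle
        cols["p_pole_w"][i] = rec.p_pole
        cols["p_pole_left_w"][i] = rec.p_pole_left
        cols["p_pole_right_w"][i] = rec.p_pole_right
        cols["p_ski_w"][i] = rec.p_ski
        cols["pct_p_pole"][i] = rec.pct_p_pole
        cols["pct_p_ski"][i] = rec.pct_p_ski
        cols["pct_p_pole_left"][i] = rec.pct_p_pole_left
        cols["pct_p_pole_right"][i] = rec.pct_p_pole_right
    for name, arr in cols.items():
        table[name] = arr


def analyze_session(
    session: SyntheticSession,
    model: "_cycles.SubtechModel | None" = None,
    label_overrides: pd.DataFrame | None = None,
    odd_lap_power_only: bool = True,
) -> SessionAnalysis:
    """Run the full analysis on one session.

    Sub-technique labels come from ``model`` when given, otherwise from the
    session's ground truth (useful for stages that are tested independently
    of the classifier).  ``label_overrides`` applies the manual-correction
    hook after classification.
    """
    table, features = _detect_and_describe_cycles(session)
    if model is not None:
        table["label"] = _cycles.classify(model, features)
    else:
        table["label"] = truth_labels_for_cycles(table, session.truth.cycles)
    if label_overrides is not None:
        table = _cycles.apply_label_overrides(table, label_overrides)
    events = _attach_contacts(session, table)
    _attach_power(session, table, odd_laps_only=odd_lap_power_only)

    master = build_master_timeline(
        protocol=session.protocol,
        intensity=session.intensity,
        hr_max=session.profile.hr_max,
        vo2max=session.profile.vo2max,
        hr=session.streams.get("hr"),
        vo2=session.streams.get("vo2"),
        tsi_leg=session.streams.get("tsi_leg"),
        tsi_arm=session.streams.get("tsi_arm"),
        cycle_table=table,
        odd_lap_power_only=odd_lap_power_only,
    )
    return SessionAnalysis(cycle_table=table, events=events, master=master)


def session_feature_corpus(
    session: SyntheticSession,
) -> tuple[np.ndarray, np.ndarray]:
    """Detected-cycle features with ground-truth labels for one session.

    Cycles whose midpoint falls outside every truth cycle are dropped.
    """
    table, features = _detect_and_describe_cycles(session)
    labels = truth_labels_for_cycles(table, session.truth.cycles)
    keep = np.array([lab is not None for lab in labels])
    return features[keep], labels[keep].astype(str)


def train_session_model(
    sessions,
    seed: int = 0,
) -> "_cycles.SubtechModel":
    """Train the sub-technique classifier on the truth-labelled cycles of
    one or more sessions."""
    xs, ys = [], []
    for s in sessions:
        x, y = session_feature_corpus(s)
        xs.append(x)
        ys.append(y)
    return _cycles.train_model(np.vstack(xs), np.concatenate(ys), seed=seed)


def classifier_holdout_accuracy(
    n_sessions: int = 20,
    base_seed: int = 1,
    protocol: ProtocolDefinition | None = None,
    holdout_fraction: float = 0.2,
    split_seed: int = 0,
) -> tuple[float, int]:
    """Held-out sub-technique accuracy over a corpus of synthetic sessions.

    Generates ``n_sessions`` sessions (seeds ``base_seed ..``, alternating
    LI/HI, default generator settings), detects cycles, extracts features,
    trains the SVM on 80% of the cycles and scores the held-out 20% against
    the ground-truth labels.  Returns ``(accuracy, n_heldout)``.
    """
    from .synthgen import generate_session

    xs, ys = [], []
    for i in range(n_sessions):
        intensity = "LI" if i % 2 == 0 else "HI"
        session = generate_session(
            protocol, intensity, seed=base_seed + i, include={"chest"}
        )
        x, y = session_feature_corpus(session)
        xs.append(x)
        ys.append(y)
    features = np.vstack(xs)
    labels = np.concatenate(ys)
    rng = np.random.default_rng(split_seed)
    idx = rng.permutation(len(labels))
    n_train = int(round((1.0 - holdout_fraction) * len(labels)))
    model = _cycles.train_model(features[idx[:n_train]], labels[idx[:n_train]],
                                seed=split_seed)
    held = idx[n_train:]
    accuracy = float(np.mean(_cycles.classify(model, features[held]) == labels[held]))
    return accuracy, len(held)
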