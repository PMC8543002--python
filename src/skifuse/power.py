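"""Centre-of-mass kinematics and pole/ski power partitioning.

Pole power is the dot product of the pole force vector with the
centre-of-mass velocity, ``P_pole = F_x v_x + F_y v_y + F_z v_z``, computed
independently per pole and summed.  The cycle work rate against gravity and
rolling friction on the inclined treadmill,

    ``P_cycle = m g v (sin(theta) + mu cos(theta))``,  theta = atan(grade),

uses the measured rolling-friction coefficient mu = 0.016; the residual
``P_ski = P_cycle - P_pole`` is attributed to ski push-offs.  Relative
shares satisfy ``%P_pole + %P_ski = 100`` and ``%P_poleleft +
%P_poleright = 100`` by construction.

The CoM comes from a reduced, configurable body-segment table: each segment
contributes ``mass_fraction x (proximal + com_fraction * (distal -
proximal))``; air resistance and kinetic-energy fluctuation terms are
deliberately excluded from the work rate (constant-speed indoor treadmill).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "GRAVITY_MS2",
    "DEFAULT_MU",
    "BodySegmentParam",
    "SegmentParamTable",
    "PowerRecord",
    "default_segment_table",
    "com_from_markers",
    "com_velocity",
    "pole_direction_from_markers",
    "pole_power",
    "cycle_work_rate",
    "partition_power",
]

GRAVITY_MS2 = 9.81
DEFAULT_MU = 0.016


@dataclass(frozen=True)
class BodySegmentParam:
    """Mass fraction and CoM position fraction of one body segment."""

    name: str
    mass_fraction: float
    com_fraction: float
    proximal: str
    distal: str


@dataclass(frozen=True)
class SegmentParamTable:
    """Body-segment parameters; mass fractions must sum to one."""

    segments: tuple[BodySegmentParam, ...]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, expected 1")

    @classmethod
    def from_mapping(cls, config) -> "SegmentParamTable":
        rows = tuple(
            BodySegmentParam(
                name=s["name"],
                mass_fraction=float(s["mass_fraction"]),
                com_fraction=float(s["com_fraction"]),
                proximal=s["proximal"],
                distal=s["distal"],
            )
            for s in config["segments"]
        )
        return cls(rows)

    @classmethod
    def from_yaml(cls, path) -> "SegmentParamTable":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_segment_table() -> SegmentParamTable:
    """The packaged reduced 3-segment table (trunk / legs / arms)."""
    text = resources.files("skifuse.data").joinpath("segment_params.yaml").read_text()
    return SegmentParamTable.from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class PowerRecord:
    """Absolute and relative pole/ski power of one cycle."""

    p_cycle: float
    p_pole: float
    p_pole_left: float
    p_pole_right: float
    p_ski: float
    pct_p_pole: float
    pct_p_ski: float
    pct_p_pole_left: float
    pct_p_pole_right: float


def _marker_xyz(markers: pd.DataFrame, name: str) -> np.ndarray:
    cols = [f"{name}_{ax}" for ax in "xyz"]
    missing = [c for c in cols if c not in markers.columns]
    if missing:
        raise KeyError(f"missing marker columns: {missing}")
    return markers[cols].to_numpy(dtype=float)


def com_from_markers(markers: pd.DataFrame, table: SegmentParamTable) -> np.ndarray:
    """Whole-body CoM position series (n x 3) from segment marker pairs.

    ``CoM = sum_i w_i * (P_i + f_i * (D_i - P_i))`` over the table's
    segments, evaluated per time sample.
    """
    com = np.zeros((len(markers), 3))
    for seg in table.segments:
        prox = _marker_xyz(markers, seg.proximal)
        dist = _marker_xyz(markers, seg.distal)
        com += seg.mass_fraction * (prox + seg.com_fraction * (dist - prox))
    return com


def com_velocity(
    positions: np.ndarray,
    rate: float,
    lowpass_hz: float | None = 10.0,
) -> np.ndarray:
    """Numerical differentiation of the CoM position (central differences,
    one-sided at the edges), optionally low-pass filtering the positions
    first (``lowpass_hz=None`` disables the filter)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if lowpass_hz is not None and lowpass_hz < rate / 2:
        sos = butter(4, lowpass_hz, btype="lowpass", fs=rate, output="sos")
        positions = sosfiltfilt(sos, positions, axis=0)
    return np.gradient(positions, 1.0 / rate, axis=0)


def pole_direction_from_markers(
    markers: pd.DataFrame, side: str
) -> np.ndarray:
    """Per-sample unit pole direction from the tip and grip markers
    (pointing from tip to grip, i.e. with a positive upward component)."""
    grip = _marker_xyz(markers, f"pole_{side}_grip")
    tip = _marker_xyz(markers, f"pole_{side}_tip")
    d = grip - tip
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def pole_power(
    axial_force: np.ndarray,
    direction: np.ndarray,
    com_velocity: np.ndarray,
) -> np.ndarray:
    """Instantaneous pole power for one side: ``(axial x direction) . v``.

    ``direction`` must be unit-norm per sample (checked to 1e-3);
    series must be aligned sample-by-sample.
    """
    axial_force = np.asarray(axial_force, dtype=float)
    direction = np.asarray(direction, dtype=float)
    com_velocity = np.asarray(com_velocity, dtype=float)
    norms = np.linalg.norm(direction, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise ValueError(f"pole direction is not unit-norm (off by {worst:.2e})")
    components = axial_force[..., None] * direction
    return np.einsum("...k,...k->...", components, com_velocity)


def cycle_work_rate(
    body_mass_kg: float,
    speed_ms: float | np.ndarray,
    grade: float,
    mu: float = DEFAULT_MU,
) -> float:
    """Treadmill work rate against gravity and rolling friction (W).

    ``P = m g v (sin(theta) + mu cos(theta))`` with ``theta = atan(grade)``;
    an array ``speed_ms`` is averaged over the cycle first.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    v = float(np.mean(speed_ms))
    if v < 0:
        raise ValueError("speed must be >= 0")
    theta = math.atan(grade)
    return body_mass_kg * GRAVITY_MS2 * v * (math.sin(theta) + mu * math.cos(theta))


def partition_power(
    p_cycle: float,
    p_pole: float,
    p_pole_left: float | None = None,
    p_pole_right: float | None = None,
) -> PowerRecord:
    """Split the cycle work rate into pole and ski shares.

    ``P_ski = P_cycle - P_pole``; ``%P_pole = 100 P_pole / P_cycle`` and
    ``%P_ski = 100 - %P_pole`` exactly.  Left/right shares are percentages
    of the summed pole power.  ``p_cycle <= 0`` leaves the partition
    undefined and raises.
    """
    if p_cycle <= 0:
        raise ValueError(f"partition undefined for P_cycle = {p_cycle}")
    if p_pole_left is None or p_pole_right is None:
        p_pole_left = 0.5 * p_pole
        p_pole_right = p_pole - p_pole_left
    pct_pole = 100.0 * p_pole / p_cycle
    if p_pole != 0.0:
        pct_left = 100.0 * p_pole_left / p_pole
    else:
        pct_left = 50.0
    return PowerRecord(
        p_cycle=p_cycle,
        p_pole=p_pole,
        p_pole_left=p_pole_left,
        p_pole_right=p_pole_right,
        p_ski=p_cycle - p_pole,
        pct_p_pole=pct_pole,
        pct_p_ski=100.0 - pct_pole,
        pct_p_pole_left=pct_left,
        pct_p_pole_right=100.0 - pct_left,
    )
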