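"""Summary statistics of a session: terrain-dependent fluctuations,
time-dependent changes, grouped means and LI-vs-HI deltas.

Two scalar statistics condense the per-second (1 Hz) traces:

* **TDF** (terrain-dependent fluctuation): the mean over laps 2-7 of the
  within-lap peak-minus-minimum of a series expressed in % of its maximum
  level.  Lap 1 is excluded because the session starts from rest.
* **TDC** (time-dependent change): the difference of within-lap means
  between the last lap and an early reference lap — lap 2 for physiological
  variables (lap 1 starts from rest), lap 1 for biomechanical/power
  variables.

"% of max level" uses the individual test-day maxima for heart rate and
oxygen uptake; for muscle oximetry, where no test-day maximum exists, the
per-session signal maximum is used (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_to_max",
    "tdf",
    "tdc",
    "aggregate_by",
    "subtech_distribution",
    "session_summary_delta",
    "FluctuationSummary",
]

PHYS_LAP_REF = (2, 7)
BIOMECH_LAP_REF = (1, 7)


class LapCoverageError(ValueError):
    """A referenced lap has no usable data."""


@dataclass(frozen=True)
class FluctuationSummary:
    """TDF / TDC of one variable for one skier and intensity."""

    variable: str
    tdf: float
    tdc: float
    lap_ref: tuple[int, int]
    n_laps: int = 6


def normalize_to_max(values: np.ndarray, basis: float | None = None) -> np.ndarray:
    """Express a series in % of its maximum level.

    ``basis`` is the individual maximum (e.g. HRmax in the series' units);
    when ``None`` the per-session maximum of the series itself is used
    (the oximetry convention here).
    """
    values = np.asarray(values, dtype=float)
    if basis is None:
        basis = np.nanmax(values)
    if not np.isfinite(basis) or basis <= 0:
        raise ValueError(f"normalization basis must be positive, got {basis}")
    return 100.0 * values / basis


def _lap_slice(values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = int(np.ceil(window[0])), int(np.ceil(window[1]))
    return values[lo:hi]


def tdf(
    values: np.ndarray,
    lap_windows: Sequence[tuple[int, float, float]],
    laps: Iterable[int] = range(2, 8),
) -> float:
    """Terrain-dependent fluctuation (%-points).

    ``values`` is the per-second normalized series indexed from session
    second 0; ``lap_windows`` is ``[(lap, start, end), ...]``.  For each
    included lap the within-lap peak minus minimum is taken and the results
    averaged.
    """
    values = np.asarray(values, dtype=float)
    laps = list(laps)
    by_lap = {lap: (s, e) for lap, s, e in lap_windows}
    deltas = []
    for lap in laps:
        if lap not in by_lap:
            raise LapCoverageError(f"lap {lap} missing from lap windows")
        chunk = _lap_slice(values, by_lap[lap])
        if len(chunk) == 0 or np.all(np.isnan(chunk)):
            raise LapCoverageError(f"lap {lap} has no data")
        deltas.append(np.nanmax(chunk) - np.nanmin(chunk))
    return float(np.mean(deltas))


def tdc(
    values: np.ndarray,
    lap_windows: Sequence[tuple[int, float, float]],
    lap_ref: tuple[int, int] = PHYS_LAP_REF,
) -> float:
    """Time-dependent change (%-points): late-lap mean minus early-lap mean.

    ``lap_ref`` is ``(2, 7)`` for physiological variables and ``(1, 7)``
    for biomechanical/power variables.
    """
    values = np.asarray(values, dtype=float)
    by_lap = {lap: (s, e) for lap, s, e in lap_windows}
    early, late = lap_ref
    means = {}
    for lap in (early, late):
        if lap not in by_lap:
            raise LapCoverageError(f"lap {lap} missing from lap windows")
        chunk = _lap_slice(values, by_lap[lap])
        if len(chunk) == 0 or np.all(np.isnan(chunk)):
            raise LapCoverageError(f"lap {lap} has no data")
        means[lap] = float(np.nanmean(chunk))
    return means[late] - means[early]


def aggregate_by(
    master: pd.DataFrame,
    keys: Sequence[str],
    min_duration_s: float = 6.0,
    values: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Grouped means/SDs of master-timeline columns.

    ``keys`` is a non-empty subset of {lap, segment, sub_technique}.  Groups
    whose total duration (seconds of data) is below ``min_duration_s`` are
    dropped — e.g. a sub-technique used for less than 6 s within a segment
    is excluded.  Missing markers are ignored in the means.
    """
    keys = list(keys)
    if not keys:
        raise ValueError("at least one grouping key is required")
    allowed = {"lap", "segment", "sub_technique", "intensity"}
    bad = set(keys) - allowed
    if bad:
        raise ValueError(f"unknown grouping keys: {sorted(bad)}")
    if values is None:
        values = [
            c for c in master.columns
            if c not in {"time_s", "lap", "segment", "intensity", "sub_technique"}
            and master[c].dtype.kind in "fiu"
        ]
    frame = master.dropna(subset=[k for k in keys if k == "sub_technique"])
    grouped = frame.groupby(keys, dropna=True, observed=True)
    n_seconds = grouped.size().rename("n_seconds")
    agg = grouped[list(values)].agg(["mean", "std"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    out = pd.concat([n_seconds, agg], axis=1).reset_index()
    return out[out["n_seconds"] >= min_duration_s].reset_index(drop=True)


def subtech_distribution(
    cycle_table: pd.DataFrame,
    windows: Sequence[tuple[str, float, float]],
) -> pd.DataFrame:
    """Percent of (cycle-covered) time per sub-technique in each window.

    ``windows`` is ``[(name, start, end), ...]``; the overlap of each
    labelled cycle with the window is accumulated and expressed as percent
    of the total covered time, so percentages sum to 100 per window.
    """
    starts = cycle_table["start"].to_numpy(dtype=float)
    ends = cycle_table["end"].to_numpy(dtype=float)
    labels = cycle_table["label"].to_numpy()
    rows = []
    for name, w0, w1 in windows:
        overlap = np.clip(np.minimum(ends, w1) - np.maximum(starts, w0), 0.0, None)
        total = overlap.sum()
        shares = {}
        for lab in pd.unique(labels):
            shares[lab] = 100.0 * overlap[labels == lab].sum() / total if total > 0 else np.nan
        rows.append({"window": name, **shares})
    return pd.DataFrame(rows).fillna(0.0)


def session_summary_delta(
    li: pd.DataFrame,
    hi: pd.DataFrame,
) -> pd.DataFrame:
    """High-minus-low-intensity session deltas per variable.

    ``li``/``hi`` are indexed by variable name with columns ``mean``,
    ``sd`` and ``kind`` (``"ratio"`` for variables on a ratio scale, whose
    change is also reported as a rounded percent of the LI mean;
    ``"percent"`` for variables already on a percentage scale, whose change
    is a %-point difference).  Variable sets must match.
    """
    missing = set(li.index) ^ set(hi.index)
    if missing:
        raise ValueError(f"variables present in only one session: {sorted(missing)}")
    out = pd.DataFrame(index=li.index)
    out["li_mean"] = li["mean"]
    out["li_sd"] = li["sd"]
    out["hi_mean"] = hi.loc[li.index, "mean"]
    out["hi_sd"] = hi.loc[li.index, "sd"]
    out["kind"] = li["kind"]
    out["delta"] = out["hi_mean"] - out["li_mean"]
    pct_raw = 100.0 * out["delta"] / out["li_mean"]
    is_ratio = out["kind"] == "ratio"
    out["pct_change_raw"] = pct_raw.where(is_ratio)
    out["pct_change"] = pct_raw.where(is_ratio).round(0)
    out["delta_unit"] = np.where(is_ratio, "native", "pp")
    return out
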