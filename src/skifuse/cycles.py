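"""Movement-cycle detection and sub-technique classification.

Cycles are segmented from the chest mediolateral acceleration: the signal is
Gaussian-smoothed and a cycle starts where the upper body is in its
"left-position", i.e. at a local minimum of the sway.  Each cycle window is
summarized by a fixed 12-dimensional feature vector and classified into one
of the four skating sub-techniques (G2, G3, G4, other) by a support vector
machine with a radial kernel; cycle length and rate follow from the
boundaries and the treadmill speed.

The feature representation is a package choice (the classifier family is
given, its inputs are not): per-axis means and variances of the three
accelerometer channels, mediolateral amplitude, harmonic descriptors of the
sway (dominant-frequency power ratio, second-harmonic and half-frequency
ratios — the half-frequency ratio captures the every-other-cycle asymmetry
of G2), the half-cycle asymmetry and the cycle duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .streams_io import SensorStream

__all__ = [
    "FEATURE_NAMES",
    "SubtechModel",
    "detect_cycles",
    "extract_features",
    "features_for_cycles",
    "train_model",
    "classify",
    "cycle_kinematics",
    "apply_label_overrides",
    "match_boundaries",
]

FEATURE_NAMES = (
    "mean_ap", "mean_ml", "mean_vt",
    "var_ap", "var_ml", "var_vt",
    "amp_ml",
    "dominant_power_ratio", "second_harmonic_ratio", "half_frequency_ratio",
    "half_cycle_asymmetry", "duration_s",
)


@dataclass
class SubtechModel:
    """Trained sub-technique classifier (feature scaling + SVM state)."""

    pipeline: Pipeline
    labels: tuple[str, ...]
    n_features: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {features.shape[1]} does not match the "
                f"model's {self.n_features}"
            )
        return self.pipeline.predict(features)


def detect_cycles(
    chest: SensorStream | np.ndarray,
    rate: float | None = None,
    sigma_s: float = 0.15,
    prominence_factor: float = 0.3,
    ml_channel: str = "acc_y",
    t_start: float | None = None,
    t_end: float | None = None,
) -> np.ndarray:
    """Cycle boundaries from the mediolateral chest acceleration.

    The channel is smoothed with a Gaussian kernel of width ``sigma_s``
    seconds and boundaries are the local minima whose prominence exceeds
    ``prominence_factor`` times the signal's standard deviation — constant
    or aperiodic stretches therefore yield no cycles.  Boundaries are
    invariant to adding a constant to the channel.

    Returns boundary times (master clock for a stream, seconds from zero
    for a raw array with ``rate``), strictly increasing.
    """
    if isinstance(chest, SensorStream):
        t = chest.master_time
        x = chest.channel(ml_channel)
        rate = chest.rate
    else:
        x = np.asarray(chest, dtype=float)
        if rate is None:
            raise ValueError("rate is required for a raw array")
        t = np.arange(len(x)) / rate
    if t_start is not None or t_end is not None:
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        m = (t >= lo) & (t < hi)
        t, x = t[m], x[m]
    if len(x) == 0:
        raise ValueError("empty signal")
    if sigma_s <= 0:
        raise ValueError(f"sigma_s must be > 0, got {sigma_s}")
    smooth = gaussian_filter1d(x, sigma_s * rate)
    sd = float(np.std(smooth))
    if sd == 0.0:
        return np.array([])
    minima, _ = find_peaks(-smooth, prominence=prominence_factor * sd)
    return t[minima]


def extract_features(
    window: pd.DataFrame | dict,
    rate: float,
) -> np.ndarray:
    """Fixed-length feature vector for one cycle window of chest channels.

    ``window`` needs ``acc_x`` (anteroposterior), ``acc_y`` (mediolateral)
    and ``acc_z`` (vertical) arrays covering one cycle.  Deterministic;
    scaling is applied from training statistics at predict time, not here.
    """
    ap = np.asarray(window["acc_x"], dtype=float)
    ml = np.asarray(window["acc_y"], dtype=float)
    vt = np.asarray(window["acc_z"], dtype=float)
    n = len(ml)
    if n < 4:
        raise ValueError(f"cycle window of {n} samples is too short")
    duration = n / rate

    ml0 = ml - ml.mean()
    tau = np.arange(n) / n  # one cycle mapped onto [0, 1)

    def _proj(k: float) -> float:
        return float(np.abs(np.mean(ml0 * np.exp(-2j * np.pi * k * tau))))

    p_half, p1, p2 = _proj(0.5), _proj(1.0), _proj(2.0)
    total_power = float(np.mean(ml0**2)) or 1e-12
    eps = 1e-12
    half_rms = np.sqrt(np.mean(ml0[: n // 2] ** 2)), np.sqrt(np.mean(ml0[n // 2:] ** 2))
    asym = (half_rms[0] - half_rms[1]) / (half_rms[0] + half_rms[1] + eps)
    return np.array(
        [
            ap.mean(), ml.mean(), vt.mean(),
            ap.var(), ml.var(), vt.var(),
            float(ml.max() - ml.min()),
            2.0 * p1**2 / total_power,
            p2 / (p1 + eps),
            p_half / (p1 + eps),
            asym,
            duration,
        ]
    )


def features_for_cycles(
    chest: SensorStream,
    boundaries: np.ndarray,
) -> np.ndarray:
    """Feature matrix (n_cycles x 12) for consecutive boundary pairs."""
    t = chest.master_time
    rate = chest.rate
    rows = []
    idx = np.searchsorted(t, boundaries)
    for i0, i1 in zip(idx[:-1], idx[1:]):
        window = {
            "acc_x": chest.channel("acc_x")[i0:i1],
            "acc_y": chest.channel("acc_y")[i0:i1],
            "acc_z": chest.channel("acc_z")[i0:i1],
        }
        rows.append(extract_features(window, rate))
    return np.array(rows).reshape(-1, len(FEATURE_NAMES))


def train_model(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    C: float = 10.0,
    gamma: str | float = "scale",
) -> SubtechModel:
    """Train the sub-technique SVM (standardized features, radial kernel,
    one-vs-one multiclass).

    Requires at least two classes and ten examples per class.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training needs >= 2 classes, got {list(classes)}")
    if counts.min() < 10:
        lacking = classes[counts < 10]
        raise ValueError(f"training needs >= 10 examples per class; short: {list(lacking)}")
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma,
                        decision_function_shape="ovo", random_state=seed)),
        ]
    )
    pipeline.fit(features, labels)
    return SubtechModel(
        pipeline=pipeline, labels=tuple(classes), n_features=features.shape[1]
    )


def classify(model: SubtechModel, features: np.ndarray) -> np.ndarray:
    """One predicted label per cycle; deterministic given model + features."""
    return model.predict(features)


def cycle_kinematics(
    boundaries: np.ndarray,
    speed_ms: np.ndarray,
    speed_rate: float = 1.0,
) -> pd.DataFrame:
    """Cycle length and rate from boundaries and the treadmill speed.

    ``CR = 60 / duration`` (cycles/min) and ``CL = mean speed x duration``
    (m), so ``CL * CR / 60`` equals the mean speed over the cycle exactly.
    ``speed_ms`` is the per-sample treadmill speed (m/s) at ``speed_rate``.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("zero- or negative-duration cycle")
    speed_t = np.arange(len(speed_ms)) / speed_rate
    rows = []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        m = (speed_t >= s) & (speed_t < e)
        v = float(np.mean(speed_ms[m])) if np.any(m) else float(
            np.interp(0.5 * (s + e), speed_t, speed_ms)
        )
        duration = e - s
        rows.append((s, e, 60.0 / duration, v * duration, v))
    return pd.DataFrame(rows, columns=["start", "end", "cr_cpm", "cl_m", "mean_speed_ms"])


def apply_label_overrides(
    cycle_table: pd.DataFrame,
    overrides: pd.DataFrame,
    tol_s: float = 0.05,
) -> pd.DataFrame:
    """Manual-correction hook: replace labels keyed by cycle start time.

    ``overrides`` has columns ``start_s`` and ``label``; a row matches the
    cycle whose start is within ``tol_s``.  Overridden labels appear
    verbatim in the returned table (a copy).
    """
    out = cycle_table.copy()
    starts = out["start"].to_numpy(dtype=float)
    for row in overrides.itertuples():
        i = int(np.argmin(np.abs(starts - row.start_s)))
        if abs(starts[i] - row.start_s) <= tol_s:
            out.iloc[i, out.columns.get_loc("label")] = row.label
    return out


def match_boundaries(
    detected: np.ndarray,
    truth: np.ndarray,
    tol_s: float = 0.1,
) -> dict:
    """Greedy nearest-neighbour matching of detected to truth boundaries.

    Returns recall, precision, F1 and the matched index pairs; used to score
    cycle detection against generator ground truth.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    used = np.zeros(len(detected), dtype=bool)
    pairs = []
    for i, tb in enumerate(truth):
        if len(detected) == 0:
            break
        j = int(np.argmin(np.abs(detected - tb)))
        if not used[j] and abs(detected[j] - tb) <= tol_s:
            used[j] = True
            pairs.append((j, i))
    tp = len(pairs)
    recall = tp / len(truth) if len(truth) else 1.0
    precision = tp / len(detected) if len(detected) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"recall": recall, "precision": precision, "f1": f1, "pairs": pairs}
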