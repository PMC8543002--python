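"""Cycle detection, feature extraction, sub-technique classification and
cycle kinematics."""

import numpy as np
import pandas as pd
import pytest

from skifuse.cycles import (
    FEATURE_NAMES,
    apply_label_overrides,
    classify,
    cycle_kinematics,
    detect_cycles,
    extract_features,
    match_boundaries,
    train_model,
)
from skifuse.pipeline import session_feature_corpus
from skifuse.synthgen import generate_session

RATE = 256.0


def _sway(cpm=40.0, duration=60.0, amp=3.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return -amp * np.cos(2 * np.pi * t * cpm / 60.0), t


class TestDetectCycles:
    def test_pure_sinusoid_minima(self):
        x, t = _sway(cpm=40.0)
        b = detect_cycles(x, rate=RATE)
        assert 38 <= len(b) <= 40  # interior minima of 40 cycles
        periods = np.diff(b)
        np.testing.assert_allclose(periods, 60.0 / 40.0, atol=2.0 / RATE)

    def test_constant_signal_yields_no_cycles(self):
        b = detect_cycles(np.full(5120, 2.5), rate=RATE)
        assert len(b) == 0

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_cycles(np.array([]), rate=RATE)

    def test_invariant_to_constant_offset(self):
        x, _ = _sway()
        b0 = detect_cycles(x, rate=RATE)
        b1 = detect_cycles(x + 17.3, rate=RATE)
        np.testing.assert_array_equal(b0, b1)

    def test_synthetic_session_f1(self, mini_chest_session):
        s = mini_chest_session
        b = detect_cycles(
            s.streams["chest"], t_start=0.0, t_end=s.protocol.total_duration
        )
        truth = np.unique(
            np.concatenate([s.truth.cycles["start"], s.truth.cycles["end"]])
        )
        m = match_boundaries(b, truth, tol_s=0.1)
        assert m["recall"] >= 0.95
        assert m["f1"] >= 0.95


class TestExtractFeatures:
    def _window(self, n=256, amp=1.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / n
        return {
            "acc_x": amp * np.sin(2 * np.pi * t),
            "acc_y": -amp * np.cos(2 * np.pi * t) + 0.01 * rng.normal(size=n),
            "acc_z": amp * np.sin(4 * np.pi * t),
        }

    def test_constant_window_zero_variance(self):
        w = {k: np.full(64, 2.0) for k in ("acc_x", "acc_y", "acc_z")}
        f = extract_features(w, RATE)
        names = list(FEATURE_NAMES)
        for var in ("var_ap", "var_ml", "var_vt"):
            assert f[names.index(var)] == 0.0

    def test_deterministic(self):
        w = self._window()
        np.testing.assert_array_equal(extract_features(w, RATE), extract_features(w, RATE))

    def test_amplitude_doubling_quadruples_variance(self):
        # oracle: direct recomputation on the doubled window
        f1 = extract_features(self._window(amp=1.0), RATE)
        f2 = extract_features(self._window(amp=2.0), RATE)
        names = list(FEATURE_NAMES)
        for var in ("var_ap", "var_vt"):
            i = names.index(var)
            assert f2[i] == pytest.approx(4.0 * f1[i], rel=1e-9)
        assert f2[names.index("var_ml")] == pytest.approx(
            4.0 * f1[names.index("var_ml")], rel=1e-2  # small noise floor
        )

    def test_short_window_rejected(self):
        w = {k: np.ones(3) for k in ("acc_x", "acc_y", "acc_z")}
        with pytest.raises(ValueError):
            extract_features(w, RATE)


@pytest.fixture(scope="module")
def corpus(mini_protocol):
    xs, ys = [], []
    for seed, intensity in ((21, "LI"), (22, "HI")):
        s = generate_session(mini_protocol, intensity, seed=seed, include={"chest"})
        x, y = session_feature_corpus(s)
        xs.append(x)
        ys.append(y)
    return np.vstack(xs), np.concatenate(ys)


class TestClassifier:
    def test_held_out_accuracy_above_99(self, corpus):
        X, y = corpus
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        n_train = int(0.8 * len(y))
        model = train_model(X[idx[:n_train]], y[idx[:n_train]], seed=0)
        acc = float(np.mean(classify(model, X[idx[n_train:]]) == y[idx[n_train:]]))
        assert acc > 0.99

    def test_training_set_memorized_when_separable(self, corpus):
        X, y = corpus
        model = train_model(X, y, seed=0)
        assert np.mean(classify(model, X) == y) == 1.0

    def test_permuted_labels_give_chance_accuracy(self, corpus):
        # oracle: permutation null — with 4 balanced classes, chance is 25%
        X, y = corpus
        rng = np.random.default_rng(3)
        per_class = min(np.bincount(pd.factorize(y)[0]))
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(y == lab), per_class, replace=False)
             for lab in np.unique(y)]
        )
        Xb, yb = X[keep], rng.permutation(y[keep])
        idx = rng.permutation(len(yb))
        n_train = int(0.8 * len(yb))
        model = train_model(Xb[idx[:n_train]], yb[idx[:n_train]], seed=0)
        acc = float(np.mean(classify(model, Xb[idx[n_train:]]) == yb[idx[n_train:]]))
        assert 0.15 <= acc <= 0.35

    def test_single_class_training_rejected(self, corpus):
        X, y = corpus
        m = y == "G3"
        with pytest.raises(ValueError, match="2 classes"):
            train_model(X[m], y[m])

    def test_feature_dimension_mismatch_rejected(self, corpus):
        X, y = corpus
        model = train_model(X, y, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            model.predict(X[:, :5])

    def test_prediction_deterministic(self, corpus):
        X, y = corpus
        model = train_model(X, y, seed=0)
        np.testing.assert_array_equal(classify(model, X), classify(model, X))


class TestCycleKinematics:
    def test_one_second_cycles_at_five_ms(self):
        boundaries = np.arange(6, dtype=float)
        speed = np.full(10, 5.0)
        table = cycle_kinematics(boundaries, speed)
        np.testing.assert_allclose(table["cr_cpm"], 60.0)
        np.testing.assert_allclose(table["cl_m"], 5.0)

    def test_cl_cr_identity_recovers_speed(self):
        rng = np.random.default_rng(1)
        boundaries = np.cumsum(rng.uniform(0.8, 1.6, 20))
        speed = rng.uniform(2.0, 6.0, 40)
        table = cycle_kinematics(boundaries, speed)
        np.testing.assert_allclose(
            table["cl_m"] * table["cr_cpm"] / 60.0, table["mean_speed_ms"], atol=1e-9
        )

    def test_zero_duration_cycle_rejected(self):
        with pytest.raises(ValueError):
            cycle_kinematics(np.array([0.0, 1.0, 1.0]), np.full(5, 3.0))

    def test_segmentwise_cr_recovery_within_2pct(self, mini_chest_session):
        s = mini_chest_session
        b = detect_cycles(s.streams["chest"], t_start=0.0, t_end=s.protocol.total_duration)
        table = cycle_kinematics(b, np.full(int(s.protocol.total_duration), 4.0))
        mid = 0.5 * (table["start"] + table["end"])
        sched = s.truth.schedule
        for w in sched.itertuples():
            in_w = table[(mid >= w.start + 1.0) & (mid < w.end - 1.0)]
            if len(in_w) < 3:
                continue
            assert np.median(in_w["cr_cpm"]) == pytest.approx(w.cycle_rate, rel=0.02)


class TestLabelOverrides:
    def test_override_round_trips(self):
        table = pd.DataFrame(
            {"start": [0.0, 1.2, 2.4], "end": [1.2, 2.4, 3.6],
             "label": ["G3", "G3", "G3"]}
        )
        overrides = pd.DataFrame({"start_s": [1.2], "label": ["other"]})
        out = apply_label_overrides(table, overrides)
        assert list(out["label"]) == ["G3", "other", "G3"]
        assert list(table["label"]) == ["G3", "G3", "G3"]  # original untouched
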