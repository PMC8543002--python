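"""Terrain-dependent fluctuation / time-dependent change statistics,
grouped aggregation and session-delta arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skifuse.metrics import (
    LapCoverageError,
    aggregate_by,
    normalize_to_max,
    session_summary_delta,
    subtech_distribution,
    tdc,
    tdf,
)

LAPS = [(lap, (lap - 1) * 180.0, lap * 180.0) for lap in range(1, 8)]


def _random_series(seed):
    rng = np.random.default_rng(seed)
    kind = seed % 3
    if kind == 0:
        return rng.uniform(0.0, 100.0, 1260)
    if kind == 1:
        return np.clip(50.0 + np.cumsum(rng.normal(size=1260)), 0.0, 100.0)
    return np.clip(70.0 + 20.0 * np.sin(np.arange(1260) / 30.0)
                   + rng.normal(scale=3.0, size=1260), 0.0, 100.0)


def _brute_force_tdf(values):
    deltas = []
    for lap in range(2, 8):
        chunk = values[(lap - 1) * 180: lap * 180]
        deltas.append(max(chunk) - min(chunk))
    return sum(deltas) / 6.0


def _brute_force_tdc(values, early, late):
    def lap_mean(lap):
        chunk = values[(lap - 1) * 180: lap * 180]
        return sum(chunk) / len(chunk)

    return lap_mean(late) - lap_mean(early)


class TestTdf:
    def test_constant_series_is_zero(self):
        assert tdf(np.full(1260, 70.0), LAPS) == 0.0

    def test_forced_peak_and_min(self):
        values = np.full(1260, 70.0)
        for lap in range(1, 8):
            values[(lap - 1) * 180 + 50] = 90.0
        assert tdf(values, LAPS) == pytest.approx(20.0)

    @given(st.integers(min_value=0, max_value=100000))
    def test_matches_brute_force_oracle(self, seed):
        values = _random_series(seed)
        assert tdf(values, LAPS) == pytest.approx(
            _brute_force_tdf(list(values)), abs=1e-12
        )

    def test_permutation_within_laps_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(40, 90, 1260)
        shuffled = values.copy()
        for lap in range(1, 8):
            seg = slice((lap - 1) * 180, lap * 180)
            shuffled[seg] = rng.permutation(shuffled[seg])
        assert tdf(shuffled, LAPS) == pytest.approx(tdf(values, LAPS), abs=1e-12)

    def test_scale_invariance_of_normalization(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(100, 190, 1260)
        basis = 195.0
        a = tdf(normalize_to_max(raw, basis), LAPS)
        b = tdf(normalize_to_max(3.0 * raw, 3.0 * basis), LAPS)
        assert a == pytest.approx(b, abs=1e-9)

    def test_missing_lap_rejected(self):
        with pytest.raises(LapCoverageError):
            tdf(np.full(1260, 50.0), LAPS[:4])


class TestTdc:
    def test_constructed_difference(self):
        values = np.full(1260, 72.0)
        values[6 * 180: 7 * 180] = 79.8
        assert tdc(values, LAPS, (2, 7)) == pytest.approx(7.8)

    def test_identical_laps_give_zero(self):
        values = np.tile(np.linspace(40, 80, 180), 7)
        assert tdc(values, LAPS, (2, 7)) == pytest.approx(0.0, abs=1e-12)
        assert tdc(values, LAPS, (1, 7)) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=100000),
           st.sampled_from([(2, 7), (1, 7)]))
    def test_matches_brute_force_oracle(self, seed, lap_ref):
        values = _random_series(seed)
        assert tdc(values, LAPS, lap_ref) == pytest.approx(
            _brute_force_tdc(list(values), *lap_ref), abs=1e-12
        )

    def test_invalid_lap_flagged(self):
        values = np.full(1260, 50.0)
        values[6 * 180:] = np.nan  # e.g. treadmill stopped in lap 7
        with pytest.raises(LapCoverageError):
            tdc(values, LAPS, (2, 7))


class TestAggregateBy:
    def _master(self, subtech_seconds):
        n = 60
        labels = np.array([None] * n, dtype=object)
        labels[:subtech_seconds] = "G2"
        labels[subtech_seconds:] = "G3"
        return pd.DataFrame(
            {
                "time_s": np.arange(n, dtype=float),
                "lap": 1,
                "segment": 1,
                "intensity": "LI",
                "sub_technique": labels,
                "pct_hr": np.full(n, 75.0),
            }
        )

    def test_below_six_seconds_excluded(self):
        out = aggregate_by(self._master(5), ["sub_technique"])
        assert "G2" not in set(out["sub_technique"])

    def test_six_seconds_included(self):
        out = aggregate_by(self._master(6), ["sub_technique"])
        assert "G2" in set(out["sub_technique"])

    def test_constant_column_mean(self):
        out = aggregate_by(self._master(30), ["sub_technique"])
        assert np.allclose(out["pct_hr_mean"], 75.0)

    def test_missing_values_ignored(self):
        m = self._master(30)
        m.loc[:9, "pct_hr"] = np.nan
        out = aggregate_by(m, ["sub_technique"])
        assert np.allclose(out["pct_hr_mean"], 75.0)

    def test_empty_key_set_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by(self._master(30), [])


class TestSubtechDistribution:
    def _cycles(self, spans):
        return pd.DataFrame(
            {
                "start": [s for s, _, _ in spans],
                "end": [e for _, e, _ in spans],
                "label": [lab for _, _, lab in spans],
            }
        )

    def test_single_label_window(self):
        table = self._cycles([(0, 10, "G3")])
        out = subtech_distribution(table, [("w", 0.0, 10.0)])
        assert out.loc[0, "G3"] == pytest.approx(100.0)

    def test_half_and_half_by_duration(self):
        table = self._cycles([(0, 5, "G2"), (5, 10, "G3")])
        out = subtech_distribution(table, [("w", 0.0, 10.0)])
        assert out.loc[0, "G2"] == pytest.approx(50.0)
        assert out.loc[0, "G3"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        bounds = np.cumsum(rng.uniform(0.5, 2.0, 40))
        labels = rng.choice(["G2", "G3", "G4", "other"], 39)
        table = self._cycles(list(zip(bounds[:-1], bounds[1:], labels)))
        out = subtech_distribution(table, [("w", bounds[0], bounds[-1])])
        total = out.drop(columns="window").iloc[0].sum()
        assert total == pytest.approx(100.0, abs=1e-9)


class TestSessionSummaryDelta:
    def _frames(self):
        li = pd.DataFrame(
            {
                "mean": [41.1, 12.7, 64.6],
                "sd": [0.8, 1.2, 3.8],
                "kind": ["ratio", "ratio", "percent"],
            },
            index=["vo2_mlkgmin", "rpe", "tsi_leg"],
        )
        hi = pd.DataFrame(
            {
                "mean": [55.9, 17.2, 58.3],
                "sd": [1.7, 1.5, 6.7],
                "kind": ["ratio", "ratio", "percent"],
            },
            index=li.index,
        )
        return li, hi

    def test_ratio_scale_delta_and_percent(self):
        out = session_summary_delta(*self._frames())
        assert out.loc["vo2_mlkgmin", "delta"] == pytest.approx(14.8)
        assert out.loc["vo2_mlkgmin", "pct_change"] == 36
        assert out.loc["rpe", "delta"] == pytest.approx(4.5)
        assert out.loc["rpe", "pct_change"] == 35

    def test_percent_scale_reports_pp(self):
        out = session_summary_delta(*self._frames())
        assert out.loc["tsi_leg", "delta"] == pytest.approx(-6.3)
        assert out.loc["tsi_leg", "delta_unit"] == "pp"
        assert np.isnan(out.loc["tsi_leg", "pct_change"])

    def test_identical_sessions_give_zero(self):
        li, _ = self._frames()
        out = session_summary_delta(li, li.copy())
        assert np.allclose(out["delta"], 0.0)

    def test_mismatched_variables_rejected(self):
        li, hi = self._frames()
        with pytest.raises(ValueError, match="only one session"):
            session_summary_delta(li, hi.drop(index="rpe"))
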