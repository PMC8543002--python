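"""CoM kinematics, pole power, treadmill work rate and power partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skifuse.power import (
    BodySegmentParam,
    SegmentParamTable,
    com_from_markers,
    com_velocity,
    cycle_work_rate,
    default_segment_table,
    partition_power,
    pole_power,
)


def _markers(points: dict[str, np.ndarray], n=1) -> pd.DataFrame:
    cols = {}
    for name, xyz in points.items():
        for ax, v in zip("xyz", xyz):
            cols[f"{name}_{ax}"] = np.full(n, float(v))
    return pd.DataFrame(cols)


def _point_segment(name, w):
    # proximal == distal, so the segment CoM is the marker point itself
    return BodySegmentParam(name, w, 0.5, f"{name}_m", f"{name}_m")


class TestComFromMarkers:
    def test_two_equal_point_masses(self):
        table = SegmentParamTable((_point_segment("a", 0.5), _point_segment("b", 0.5)))
        markers = _markers({"a_m": (0, 0, 0), "b_m": (2, 0, 0)})
        np.testing.assert_allclose(com_from_markers(markers, table)[0], [1.0, 0.0, 0.0])

    def test_single_segment_midpoint(self):
        table = SegmentParamTable(
            (BodySegmentParam("leg", 1.0, 0.5, "leg_p", "leg_d"),)
        )
        markers = _markers({"leg_p": (0, 0, 0), "leg_d": (0, 0, 2)})
        np.testing.assert_allclose(com_from_markers(markers, table)[0], [0.0, 0.0, 1.0])

    def test_random_body_matches_brute_force(self):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(5))
        f = rng.uniform(0.2, 0.8, 5)
        segs = tuple(
            BodySegmentParam(f"s{i}", w[i], f[i], f"s{i}_p", f"s{i}_d")
            for i in range(5)
        )
        table = SegmentParamTable(segs)
        points = {}
        for i in range(5):
            points[f"s{i}_p"] = rng.normal(size=3)
            points[f"s{i}_d"] = rng.normal(size=3)
        markers = _markers(points)
        # oracle: explicit weighted sum
        expected = sum(
            w[i] * (points[f"s{i}_p"] + f[i] * (points[f"s{i}_d"] - points[f"s{i}_p"]))
            for i in range(5)
        )
        np.testing.assert_allclose(com_from_markers(markers, table)[0], expected, atol=1e-9)

    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SegmentParamTable((_point_segment("a", 0.5), _point_segment("b", 0.4)))

    def test_missing_marker_rejected(self):
        table = default_segment_table()
        with pytest.raises(KeyError):
            com_from_markers(pd.DataFrame({"trunk_prox_x": [0.0]}), table)


class TestComVelocity:
    def test_linear_position_gives_constant_slope(self):
        t = np.arange(200) / 200.0
        pos = np.column_stack([2.0 * t, np.zeros_like(t), np.zeros_like(t)])
        v = com_velocity(pos, 200.0, lowpass_hz=None)
        np.testing.assert_allclose(v[:, 0], 2.0, atol=1e-9)

    def test_constant_position_gives_zero(self):
        pos = np.ones((100, 3))
        v = com_velocity(pos, 200.0, lowpass_hz=None)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_sine_amplitude_matches_analytic_derivative(self):
        # oracle: d/dt A sin(w t) = A w cos(w t)
        rate, freq, amp = 200.0, 2.0, 0.15
        t = np.arange(int(3 * rate)) / rate
        pos = np.column_stack([amp * np.sin(2 * np.pi * freq * t),
                               np.zeros_like(t), np.zeros_like(t)])
        v = com_velocity(pos, rate, lowpass_hz=None)
        expected = amp * 2 * np.pi * freq
        assert np.max(v[10:-10, 0]) == pytest.approx(expected, rel=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            com_velocity(np.ones((2, 3)), 100.0)


class TestPolePower:
    def test_forward_force_times_forward_velocity(self):
        p = pole_power(np.array([10.0]), np.array([[1.0, 0, 0]]), np.array([[2.0, 0, 0]]))
        assert p[0] == pytest.approx(20.0)

    def test_orthogonal_force_gives_zero(self):
        p = pole_power(np.array([10.0]), np.array([[0, 0, 1.0]]), np.array([[2.0, 0, 0]]))
        assert p[0] == pytest.approx(0.0)

    def test_random_series_match_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        n = 500
        f = rng.uniform(0, 300, n)
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        v = rng.normal(size=(n, 3))
        p = pole_power(f, d, v)
        oracle = np.array(
            [sum(f[i] * d[i, k] * v[i, k] for k in range(3)) for i in range(n)]
        )
        np.testing.assert_allclose(p, oracle, atol=1e-9)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_bilinear_in_force(self, c):
        rng = np.random.default_rng(2)
        f = rng.uniform(0, 100, 50)
        d = np.tile([[0.4, 0.0, np.sqrt(1 - 0.16)]], (50, 1))
        v = rng.normal(size=(50, 3))
        np.testing.assert_allclose(
            pole_power(c * f, d, v), c * pole_power(f, d, v), rtol=1e-9
        )

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            pole_power(np.array([1.0]), np.array([[1.0, 1.0, 0.0]]), np.zeros((1, 3)))


class TestCycleWorkRate:
    def test_level_frictionless_is_zero(self):
        assert cycle_work_rate(80.0, 3.0, 0.0, mu=0.0) == pytest.approx(0.0)

    def test_gravity_term_alone(self):
        # oracle: 80 * 9.81 * 3 * sin(atan(0.12)) = 280.52 W
        assert cycle_work_rate(80.0, 3.0, 0.12, mu=0.0) == pytest.approx(280.52, abs=0.05)

    def test_gravity_plus_rolling_friction(self):
        # oracle: 80 * 9.81 * 3 * (sin + 0.016 cos)(atan 0.12) = 317.93 W
        assert cycle_work_rate(80.0, 3.0, 0.12, mu=0.016) == pytest.approx(317.93, abs=0.05)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            cycle_work_rate(80.0, -1.0, 0.05)


class TestPartitionPower:
    def test_table_style_example(self):
        rec = partition_power(100.0, 55.7)
        assert rec.pct_p_pole == pytest.approx(55.7)
        assert rec.pct_p_ski == pytest.approx(44.3)

    def test_no_poling_gives_all_ski(self):
        rec = partition_power(120.0, 0.0)
        assert rec.pct_p_ski == 100.0

    @given(
        p_cycle=st.floats(min_value=1.0, max_value=500.0),
        pole_frac=st.floats(min_value=0.0, max_value=1.2),
        left_frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_conservation_exact(self, p_cycle, pole_frac, left_frac):
        p_pole = pole_frac * p_cycle
        rec = partition_power(
            p_cycle, p_pole, left_frac * p_pole, (1 - left_frac) * p_pole
        )
        assert rec.pct_p_pole + rec.pct_p_ski == 100.0
        assert rec.pct_p_pole_left + rec.pct_p_pole_right == 100.0
        assert rec.p_ski == pytest.approx(p_cycle - p_pole, rel=1e-12, abs=1e-12)

    def test_nonpositive_work_rate_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            partition_power(0.0, 10.0)


class TestSessionPowerRecovery:
    def test_per_cycle_recovery_within_3pct(self, li_session, li_analysis):
        """Per-cycle pole power from streams vs generator truth, away from
        sub-technique transitions; the mean over all cycles is also bounded."""
        table = li_analysis.cycle_table.dropna(subset=["pct_p_pole"])
        truth = li_session.truth.power
        t_start = truth["start"].to_numpy()
        joins = np.concatenate(
            [li_session.truth.schedule["start"], li_session.truth.schedule["end"]]
        )
        rel_errs, interior = [], []
        for c in table.itertuples():
            j = int(np.argmin(np.abs(t_start - c.start)))
            row = truth.iloc[j]
            if abs(row["start"] - c.start) > 0.2:
                continue
            err = abs(c.p_pole_w - row["p_pole"]) / row["p_pole"]
            rel_errs.append(err)
            near_join = np.min(np.abs(joins - c.start)) < 2.0 or (
                np.min(np.abs(joins - c.end)) < 2.0
            )
            if not near_join:
                interior.append(err)
        assert len(interior) > 100
        assert np.max(interior) <= 0.03
        assert np.mean(rel_errs) <= 0.03

    def test_power_only_on_odd_laps(self, li_analysis):
        table = li_analysis.cycle_table
        even = table[table["lap"] % 2 == 0]
        assert even["pct_p_pole"].isna().all()
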