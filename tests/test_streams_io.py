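"""Stream I/O, synchronization-jump detection, 1 Hz reduction and the
master timeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import skifuse as sf
from skifuse.streams_io import (
    CoverageError,
    SensorStream,
    StreamFormatError,
    SyncDetectionError,
    build_master_timeline,
    detect_sync_jumps,
    resample_1hz,
)
from skifuse.synthgen import generate_session


def _stream(values, rate=256.0, placement="chest", channel="acc_z", t0=0.0):
    t = np.arange(len(values)) / rate
    return SensorStream(
        placement=placement, rate=rate, t0=t0,
        data=pd.DataFrame({"time_s": t, channel: values}),
    )


class TestRoundTrip:
    def test_three_sample_fixture(self, tmp_path):
        s = _stream([1.0, 2.0, 3.0], rate=10.0)
        path = tmp_path / "s.csv"
        sf.write_stream(s, path)
        back = sf.read_stream(path)
        assert len(back) == 3

    def test_values_and_metadata_preserved(self, tmp_path):
        rng = np.random.default_rng(0)
        s = _stream(rng.normal(size=100), rate=50.0, placement="ski_L", t0=-1.25)
        path = tmp_path / "ski.csv"
        sf.write_stream(s, path)
        back = sf.read_stream(path)
        assert back.placement == "ski_L"
        assert back.rate == 50.0
        assert back.t0 == -1.25
        np.testing.assert_allclose(
            back.channel("acc_z"), s.channel("acc_z"), atol=1e-9
        )

    def test_shuffled_timestamps_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,acc_z\n0.0,1\n0.5,2\n0.1,3\n")
        with pytest.raises(StreamFormatError):
            sf.read_stream(path)

    def test_missing_time_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("acc_z\n1\n2\n")
        with pytest.raises(StreamFormatError):
            sf.read_stream(path)


class TestSyncJumps:
    def _with_spikes(self, times, noise_sd=0.0, rate=256.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(10 * rate)) / rate
        x = 9.81 + rng.normal(0.0, noise_sd or 1e-3, len(t))
        for tj in times:
            x += 20.0 * np.exp(-0.5 * ((t - tj) / 0.01) ** 2)
        return _stream(x, rate=rate)

    def test_clean_spikes_recovered(self):
        s = self._with_spikes([2.0, 4.0, 6.0])
        found = detect_sync_jumps(s)
        np.testing.assert_allclose(found, [2.0, 4.0, 6.0], atol=1.0 / 256)

    def test_flat_signal_reports_zero_found(self):
        s = _stream(np.full(2560, 9.81))
        with pytest.raises(SyncDetectionError) as err:
            detect_sync_jumps(s)
        assert err.value.found == 0

    def test_jittered_noisy_spikes_within_two_samples(self):
        # oracle: argmax of the signal inside each injection window
        rng = np.random.default_rng(42)
        times = np.array([2.0, 4.0, 6.0]) + rng.uniform(-0.02, 0.02, 3)
        s = self._with_spikes(times, noise_sd=0.1 * 9.81 / 10, seed=42)
        t = s.data["time_s"].to_numpy()
        x = s.channel("acc_z")
        oracle = []
        for tj in times:
            m = np.abs(t - tj) < 0.05
            oracle.append(t[m][np.argmax(x[m])])
        found = detect_sync_jumps(s)
        np.testing.assert_allclose(found, sorted(oracle), atol=2.0 / 256)

    def test_generator_offsets_recovered(self, mini_protocol):
        offset = 0.523
        s = generate_session(
            mini_protocol, "LI", seed=9, include={"chest"},
            stream_offsets={"chest": offset},
        )
        chest = s.streams["chest"]
        local = detect_sync_jumps(chest)
        # file-local jump time minus known master jump time = applied offset
        est = local - s.truth.sync_jumps
        np.testing.assert_allclose(est, offset, atol=2.0 / 256)


class TestResample:
    def test_constant_signal(self):
        s = _stream(np.full(256 * 3, 5.0))
        out = resample_1hz(s, n_seconds=3)
        np.testing.assert_array_equal(out, [5.0, 5.0, 5.0])

    def test_ramp_mean_is_midpoint(self):
        # oracle: arithmetic mean of the integers 0..255
        s = _stream(np.arange(256.0))
        out = resample_1hz(s, n_seconds=1)
        assert out[0] == pytest.approx(127.5)

    def test_two_second_window_on_constant(self):
        s = _stream(np.full(40, 3.3), rate=10.0, placement="tsi_leg")
        out = resample_1hz(s, window=2, n_seconds=3)
        assert out[0] == pytest.approx(out[1]) == pytest.approx(3.3)

    def test_empty_bins_are_nan(self):
        s = _stream(np.ones(10), rate=10.0)
        out = resample_1hz(s, n_seconds=3)
        assert out[0] == 1.0 and np.isnan(out[2])

    @given(st.floats(min_value=-50, max_value=50))
    def test_commutes_with_constant_shift(self, c):
        rng = np.random.default_rng(0)
        x = rng.normal(size=512)
        base = resample_1hz(_stream(x), n_seconds=2)
        shifted = resample_1hz(_stream(x + c), n_seconds=2)
        np.testing.assert_allclose(shifted, base + c, atol=1e-9)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            resample_1hz(_stream(np.ones(10)), window=3)


class TestMasterTimeline:
    def test_full_session_row_count(self, li_analysis):
        assert len(li_analysis.master) == 1260

    def test_lap_segment_match_protocol_lookup(self, li_analysis, protocol):
        m = li_analysis.master
        for row in m.sample(40, random_state=0).itertuples():
            w = sf.segment_at(protocol, row.time_s)
            assert (row.lap, row.segment) == (w.lap, w.segment)

    def test_hr_at_max_gives_100_percent(self, mini_protocol):
        n = int(mini_protocol.total_duration)
        hr = SensorStream(
            placement="hr", rate=1.0,
            data=pd.DataFrame({"time_s": np.arange(n, dtype=float),
                               "bpm": np.full(n, 190.0)}),
        )
        m = build_master_timeline(
            mini_protocol, "LI", hr_max=190.0, vo2max=70.0, hr=hr
        )
        np.testing.assert_allclose(m["pct_hr"], 100.0)

    def test_short_stream_raises_coverage_error(self, mini_protocol):
        hr = SensorStream(
            placement="hr", rate=1.0,
            data=pd.DataFrame({"time_s": np.arange(30.0), "bpm": np.full(30, 120.0)}),
        )
        with pytest.raises(CoverageError):
            build_master_timeline(mini_protocol, "LI", hr_max=190.0, vo2max=70.0, hr=hr)

    def test_no_analysis_column_dropped(self, li_analysis):
        from skifuse.streams_io import MASTER_COLUMNS

        assert set(MASTER_COLUMNS) <= set(li_analysis.master.columns)

    def test_even_laps_carry_power_missing_markers(self, li_analysis):
        m = li_analysis.master
        even = m[m["lap"] % 2 == 0]
        assert even["pct_p_pole"].isna().all()
        odd = m[(m["lap"] % 2 == 1) & (m["segment"] < 4)]
        assert odd["pct_p_pole"].notna().mean() > 0.8

    def test_percentage_columns_in_range(self, li_analysis):
        m = li_analysis.master
        for col in ("pct_hr", "pct_vo2", "pct_p_pole", "pct_p_ski"):
            v = m[col].dropna()
            assert ((v >= 0) & (v <= 110)).all(), col
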