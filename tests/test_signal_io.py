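"""I/O round-trips, synchronisation, notch filtering and windowing."""

import numpy as np
import pytest

from cogload.errors import (
    InvalidArgumentError,
    LowConfidenceSyncError,
    MissingChannelError,
    ParseError,
)
from cogload.signal_io import (
    Channel,
    MultimodalRecording,
    ProtocolBlock,
    ProtocolLog,
    estimate_sync_offset,
    notch_filter,
    read_e4_export,
    read_muse_csv,
    segment_windows,
    write_e4_export,
    write_muse_csv,
)
from cogload.eeg_features import band_power


class TestE4Export:
    def test_round_trip_identity(self, tmp_path, tiny_session):
        rec, _ = tiny_session
        write_e4_export(rec, tmp_path)
        channels = read_e4_export(tmp_path)
        for name in ("temp", "eda", "ppg_e4", "acc_x", "acc_y", "acc_z"):
            orig = rec.channels[name]
            got = channels[name]
            assert got.fs == orig.fs
            assert got.start_time == pytest.approx(orig.start_time, abs=1e-6)
            np.testing.assert_allclose(got.samples, orig.samples, rtol=1e-9)

    def test_header_rate_is_respected(self, tmp_path):
        (tmp_path / "EDA.csv").write_text("1700000000.000000\n4\n0.5\n0.6\n")
        for f in ("TEMP.csv", "BVP.csv"):
            (tmp_path / f).write_text("1700000000.000000\n4\n0.0\n0.0\n")
        (tmp_path / "ACC.csv").write_text(
            "1700000000.0, 1700000000.0, 1700000000.0\n32, 32, 32\n0, 0, 0\n")
        channels = read_e4_export(tmp_path)
        assert channels["eda"].fs == 4.0

    def test_missing_file_raises_missing_channel(self, tmp_path):
        with pytest.raises(MissingChannelError):
            read_e4_export(tmp_path)

    def test_malformed_header_names_file(self, tmp_path, tiny_session):
        rec, _ = tiny_session
        write_e4_export(rec, tmp_path)
        (tmp_path / "EDA.csv").write_text("not-a-number\n4\n0.5\n")
        with pytest.raises(ParseError, match="EDA.csv"):
            read_e4_export(tmp_path)

    def test_acc_rows_become_three_equal_length_channels(self, tmp_path,
                                                         tiny_session):
        rec, _ = tiny_session
        write_e4_export(rec, tmp_path)
        channels = read_e4_export(tmp_path)
        lens = {len(channels[f"acc_{ax}"].samples) for ax in "xyz"}
        assert len(lens) == 1


class TestMuseCsv:
    def test_round_trip_identity(self, tmp_path, tiny_session):
        rec, _ = tiny_session
        path = tmp_path / "muse.csv"
        write_muse_csv(rec, path)
        channels = read_muse_csv(path)
        for name in ("eeg_af7", "eeg_af8", "eeg_tp9", "eeg_tp10",
                     "gyro_x", "gyro_y", "gyro_z", "ppg_muse"):
            orig = rec.channels[name]
            got = channels[name]
            assert got.fs == pytest.approx(orig.fs, abs=1e-5)
            np.testing.assert_allclose(got.samples, orig.samples, rtol=1e-9)

    def test_sample_count_follows_rate(self, tmp_path):
        import pandas as pd

        t = np.arange(2560) / 256.0
        frames = [pd.DataFrame({"timestamp": t, "channel": lbl,
                                "value": np.sin(t)})
                  for lbl in ("AF7", "AF8", "TP9", "TP10")]
        path = tmp_path / "muse.csv"
        pd.concat(frames).to_csv(path, index=False)
        channels = read_muse_csv(path)
        assert len(channels["eeg_af7"].samples) == 2560
        assert channels["eeg_af7"].fs == pytest.approx(256.0)

    def test_incomplete_montage_names_missing_channels(self, tmp_path):
        import pandas as pd

        t = np.arange(512) / 256.0
        pd.DataFrame({"timestamp": t, "channel": "AF7", "value": t}).to_csv(
            tmp_path / "muse.csv", index=False)
        with pytest.raises(ParseError, match="AF8.*TP9.*TP10"):
            read_muse_csv(tmp_path / "muse.csv")

    def test_unknown_channel_name_rejected(self, tmp_path):
        import pandas as pd

        t = np.arange(512) / 256.0
        pd.DataFrame({"timestamp": t, "channel": "Cz", "value": t}).to_csv(
            tmp_path / "muse.csv", index=False)
        with pytest.raises(ParseError, match="Cz"):
            read_muse_csv(tmp_path / "muse.csv")


class TestSyncOffset:
    @staticmethod
    def _burst_channel(name, fs, start, seed=0, n_s=60.0):
        rng = np.random.default_rng(seed)
        n = int(n_s * fs)
        x = 0.05 * rng.standard_normal(n)
        t = np.arange(n) / fs
        burst = np.sin(2 * np.pi * 4.0 * t[: int(3 * fs)])
        x[: len(burst)] += 5.0 * burst
        return Channel(name, x, fs, start)

    def test_identical_signals_give_zero_offset(self):
        ch = self._burst_channel("gyro_x", 50.0, 1000.0)
        assert estimate_sync_offset(ch, ch) == pytest.approx(0.0, abs=1 / 32)

    def test_known_offset_recovered(self):
        a = self._burst_channel("gyro_x", 50.0, 1000.0, seed=1)
        b = self._burst_channel("acc_x", 32.0, 1002.5, seed=2)
        offset = estimate_sync_offset(a, b)
        assert offset == pytest.approx(2.5, abs=1 / 32)

    def test_uncorrelated_noise_raises_low_confidence(self, rng):
        a = Channel("a", rng.standard_normal(50 * 60), 50.0, 0.0)
        b = Channel("b", rng.standard_normal(32 * 60), 32.0, 0.0)
        with pytest.raises(LowConfidenceSyncError):
            estimate_sync_offset(a, b)

    def test_sync_idempotent_after_correction(self, tiny_session):
        from cogload.signal_io import motion_magnitude, synchronise

        rec, _ = tiny_session
        rec2, _ = synchronise(rec)
        residual = estimate_sync_offset(motion_magnitude(rec2, "gyro"),
                                        motion_magnitude(rec2, "acc"))
        assert residual == pytest.approx(0.0, abs=1 / 32)

    def test_short_signals_rejected(self, rng):
        a = Channel("a", rng.standard_normal(50 * 5), 50.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            estimate_sync_offset(a, a)


class TestNotchFilter:
    def test_50hz_sine_attenuated_below_one_percent(self):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        y = notch_filter(Channel("eeg_af7", x, fs, 0.0)).samples
        assert np.sum(y ** 2) < 0.01 * np.sum(x ** 2)

    def test_10hz_sine_passes_within_two_percent(self):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = notch_filter(Channel("eeg_af7", x, fs, 0.0)).samples
        assert np.sum(y ** 2) == pytest.approx(np.sum(x ** 2), rel=0.02)

    def test_zero_signal_stays_zero(self):
        y = notch_filter(Channel("eeg_af7", np.zeros(2560), 256.0, 0.0)).samples
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_low_rate_channel_passes_unchanged(self):
        x = np.sin(np.arange(240) / 4.0)
        ch = Channel("eda", x, 4.0, 0.0)
        out = notch_filter(ch)
        np.testing.assert_array_equal(out.samples, x)


class TestSegmentWindows:
    @staticmethod
    def _recording(duration_s, start=0.0):
        channels = {
            "eeg_af7": Channel("eeg_af7", np.zeros(int(256 * duration_s)), 256.0, start),
            "eda": Channel("eda", np.zeros(int(4 * duration_s)), 4.0, start),
        }
        return MultimodalRecording("P01", "s1", "controlled", channels)

    @staticmethod
    def _log(*blocks):
        return ProtocolLog([
            ProtocolBlock(act, start, end, "controlled", 3, 3)
            for act, start, end in blocks
        ])

    @pytest.mark.parametrize("block_s,expected", [(600.0, 10), (90.0, 1), (59.0, 0)])
    def test_window_count_truncates_partial_windows(self, block_s, expected):
        rec = self._recording(block_s)
        log = self._log(("Relaxation", 0.0, block_s))
        windows = segment_windows(rec, log)
        assert len(windows) == expected
        assert all(w.activity == "Relaxation" for w in windows)

    def test_windows_never_straddle_blocks(self):
        rec = self._recording(180.0)
        log = self._log(("Relaxation", 0.0, 90.0), ("Load", 90.0, 180.0))
        windows = segment_windows(rec, log)
        assert len(windows) == 2
        assert [w.start_time for w in windows] == [0.0, 90.0]

    def test_eeg_slice_length_is_rate_times_window(self, tiny_session):
        rec, log = tiny_session
        from cogload.signal_io import synchronise

        rec, _ = synchronise(rec)
        windows = segment_windows(rec, log)
        assert windows and all(
            len(w.channels["eeg_af7"]) == 60 * 256 for w in windows)

    def test_windows_inherit_block_labels(self, tiny_session):
        from cogload.signal_io import synchronise

        rec, log = tiny_session
        rec, _ = synchronise(rec)
        windows = segment_windows(rec, log)
        by_act = {w.activity: w.workload_response for w in windows}
        assert by_act["Relaxation"] == 1
        assert by_act["Load"] == 5

    def test_empty_overlap_returns_empty_list(self):
        rec = self._recording(120.0, start=0.0)
        log = self._log(("Relaxation", 1000.0, 1120.0))
        assert segment_windows(rec, log) == []

    def test_windowing_conserves_block_budget(self, tiny_session):
        from cogload.signal_io import synchronise

        rec, log = tiny_session
        rec, _ = synchronise(rec)
        windows = segment_windows(rec, log)
        total_blocks = sum(b.end - b.start for b in log.blocks)
        assert len(windows) * 60.0 <= total_blocks
        assert total_blocks - len(windows) * 60.0 < 60.0 * len(log.blocks)
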