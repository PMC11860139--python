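"""Recording I/O, rate inference, resampling, windowing and splitting."""

import numpy as np
import pandas as pd
import pytest

from gaitguard.signals_io import (
    CHANNELS,
    DialectError,
    G_TO_MS2,
    GaitRecording,
    LabeledDataset,
    ParseError,
    Window,
    aggregate_shape,
    infer_sampling_rate,
    read_recording,
    resample,
    segment,
    split_by_ratio,
    windows_to_dataset,
)

DIALECT = {
    "columns": {ch: ch.upper() for ch in CHANNELS},
    "label": "gait",
    "subject_id": "s1",
    "rate": 100.0,
}


def _write_csv(path, n=400, timestamps=None, accel_scale=1.0):
    rng = np.random.default_rng(5)
    scale = np.array([accel_scale] * 3 + [1.0] * 3)
    df = pd.DataFrame(rng.normal(size=(n, 6)) * scale,
                      columns=[ch.upper() for ch in CHANNELS])
    if timestamps is not None:
        df["T"] = timestamps
    df.to_csv(path, index=False)
    return df


class TestReadRecording:
    def test_passthrough(self, tmp_path):
        path = tmp_path / "rec.csv"
        df = _write_csv(path, n=400)
        rec = read_recording(path, DIALECT)
        assert rec.samples.shape == (400, 6)
        np.testing.assert_allclose(rec.samples[:, 0], df["AX"].to_numpy())

    def test_g_to_ms2_applied_to_accel_only(self, tmp_path):
        path = tmp_path / "rec.csv"
        df = _write_csv(path)
        rec = read_recording(path, {**DIALECT, "accel_in_g": True})
        np.testing.assert_allclose(rec.samples[:, :3],
                                   df[["AX", "AY", "AZ"]].to_numpy() * G_TO_MS2)
        np.testing.assert_allclose(rec.samples[:, 3:],
                                   df[["GX", "GY", "GZ"]].to_numpy())

    def test_decreasing_timestamp_names_row(self, tmp_path):
        ts = np.arange(400) * 0.01
        ts[10] = ts[9] - 0.001  # goes backwards at row 10
        path = tmp_path / "rec.csv"
        _write_csv(path, timestamps=ts)
        dialect = {**DIALECT, "timestamp": "T"}
        with pytest.raises(ParseError, match="row 10"):
            read_recording(path, dialect)

    def test_missing_column_is_config_error(self, tmp_path):
        path = tmp_path / "rec.csv"
        _write_csv(path)
        bad = {**DIALECT, "columns": {**DIALECT["columns"], "gz": "NOPE"}}
        with pytest.raises(DialectError):
            read_recording(path, bad)

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "rec.csv"
        df = _write_csv(path)
        df["AY"] = df["AY"].astype(object)
        df.loc[7, "AY"] = "oops"
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match="row 7"):
            read_recording(path, DIALECT)

    def test_short_recording_warns_but_returns(self, tmp_path):
        path = tmp_path / "rec.csv"
        _write_csv(path, n=150)
        with pytest.warns(UserWarning, match="150 samples"):
            rec = read_recording(path, DIALECT)
        assert len(rec.samples) == 150


class TestInferSamplingRate:
    @pytest.mark.parametrize("step, expected", [(0.01, 100), (0.02, 50)])
    def test_uniform_grid(self, step, expected):
        assert infer_sampling_rate(np.arange(100) * step) == expected

    def test_median_robust_to_single_gap(self):
        # 98 steps of 10 ms plus one 30 ms dropout gap
        diffs = np.array([0.01] * 98 + [0.03])
        ts = np.concatenate([[0.0], np.cumsum(diffs)])
        assert int(np.round(1 / np.median(np.diff(ts)))) == 100  # oracle
        assert infer_sampling_rate(ts) == 100

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            infer_sampling_rate([0.0, 0.2, 0.1])


class TestResample:
    def _rec(self, samples, rate):
        return GaitRecording(np.column_stack([samples] * 6), rate, "gait", "s")

    def test_upsample_length(self):
        rec = self._rec(np.zeros(100), 50.0)  # 1.98 s of signal
        out = resample(rec, 100.0)
        assert len(out.samples) == 199
        assert out.rate == 100.0

    def test_constant_channel_stays_constant(self):
        rec = self._rec(np.full(100, 3.25), 50.0)
        out = resample(rec, 100.0)
        np.testing.assert_allclose(out.samples, 3.25)

    def test_identity_when_rates_match(self):
        rec = self._rec(np.sin(np.arange(100)), 100.0)
        out = resample(rec, 100.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_ramp_midpoints_are_neighbor_means(self):
        ramp = np.linspace(0.0, 1.0, 100)
        out = resample(self._rec(ramp, 50.0), 100.0)
        new = out.samples[:, 0]
        np.testing.assert_allclose(new[0::2], ramp[:len(new[0::2])], atol=1e-12)
        mids = (ramp[:-1] + ramp[1:]) / 2
        np.testing.assert_allclose(new[1::2], mids[:len(new[1::2])], atol=1e-12)


class TestSegment:
    def _rec(self, n):
        return GaitRecording(np.random.default_rng(0).normal(size=(n, 6)),
                             100.0, "gait", "s")

    @pytest.mark.parametrize("n, expected", [(1000, 5), (399, 1), (199, 0), (200, 1)])
    def test_window_count_is_floor(self, n, expected):
        wins = segment(self._rec(n))
        assert len(wins) == expected
        for w in wins:
            assert w.values.shape == (200, 6)

    def test_windows_record_origin(self):
        wins = segment(self._rec(600))
        assert [w.origin for w in wins] == [("s", 0), ("s", 200), ("s", 400)]

    def test_rejects_wrong_rate(self):
        rec = GaitRecording(np.zeros((400, 6)), 50.0, "gait", "s")
        with pytest.raises(ValueError, match="resample"):
            segment(rec)


class TestSplitByRatio:
    def test_ratio_within_group(self):
        groups = ["a"] * 10
        split = split_by_ratio(groups, ratio=0.8, seed=1)
        assert (split == "train").sum() == 8
        assert (split == "test").sum() == 2

    def test_unseen_group_fully_held_out(self):
        groups = ["a"] * 10 + ["b"] * 4
        split = split_by_ratio(groups, seed=1, unseen_groups={"b"})
        assert set(split[10:]) == {"unseen"}
        assert (split[:10] == "train").sum() == 8

    def test_deterministic_under_seed(self):
        groups = ["a"] * 7 + ["b"] * 9
        s1 = split_by_ratio(groups, seed=42)
        s2 = split_by_ratio(groups, seed=42)
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, split_by_ratio(groups, seed=43))

    def test_partition_property(self, tiny_benchmark):
        counts = {s: int((tiny_benchmark.split == s).sum())
                  for s in ("train", "test", "unseen")}
        assert sum(counts.values()) == len(tiny_benchmark)


class TestBookkeeping:
    def test_multi_corpus_training_pool_shape(self):
        # per-corpus training window counts of a three-corpus pool
        assert aggregate_shape([1168, 378, 11948]) == (13494, 200, 6)

    def test_multi_corpus_unseen_pool_shape(self):
        assert aggregate_shape([1393, 3336, 7852, 6295]) == (18876, 200, 6)


class TestLabeledDataset:
    def test_binary_and_multiclass_maps_consistent(self, tiny_benchmark):
        multi = tiny_benchmark.multiclass_labels()
        binary = tiny_benchmark.binary_labels()
        np.testing.assert_array_equal(binary == 1, multi == 0)

    def test_hdf5_round_trip(self, tiny_benchmark, tmp_path):
        path = tmp_path / "ds.h5"
        tiny_benchmark.to_hdf5(path)
        back = LabeledDataset.from_hdf5(path)
        np.testing.assert_array_equal(back.windows, tiny_benchmark.windows)
        np.testing.assert_array_equal(back.labels, tiny_benchmark.labels)
        np.testing.assert_array_equal(back.split, tiny_benchmark.split)

    def test_window_invariants_enforced(self):
        with pytest.raises(ValueError):
            Window(np.zeros((199, 6)), "gait")
        with pytest.raises(ValueError):
            Window(np.full((200, 6), np.nan), "gait")

    def test_windows_to_dataset_groups(self):
        wins = [Window(np.zeros((200, 6)), "gait", ("s1", i * 200)) for i in range(3)]
        ds = windows_to_dataset(wins)
        assert set(ds.groups) == {"s1"}
        assert len(ds) == 3
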