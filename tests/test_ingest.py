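import json

import numpy as np
import pandas as pd
import pytest

from conftest import make_series
from glucovar.ingest import SplitSpec, clean, read_records, resample_to_grid, split_train_test
from glucovar.simulate import ArtifactConfig, RawRecordSet, SimConfig, generate_trace, inject_artifacts


class TestReadRecords:
    def test_csv_header_skipped(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("timestamp,glucose_mgdl\n2021-01-01T00:00:00Z,100\n2021-01-01T00:05:00Z,110\n")
        rec = read_records(p)
        assert len(rec) == 2

    def test_unparsable_value_retained_raw(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("timestamp,glucose_mgdl\n2021-01-01T00:00:00Z,abc\n")
        rec = read_records(p)
        assert rec.records[0][1] == "abc"

    def test_mmol_converted_to_mgdl(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("timestamp,glucose_mmoll\n2021-01-01T00:00:00Z,5.5\n")
        rec = read_records(p, unit="mmoll")
        assert float(rec.records[0][1]) == pytest.approx(99.088, abs=1e-9)

    def test_nightscout_json(self, tmp_path):
        p = tmp_path / "entries.json"
        p.write_text(json.dumps([
            {"dateString": "2021-01-01T00:00:00Z", "sgv": 105},
            {"dateString": "2021-01-01T00:05:00Z", "sgv": 108},
        ]))
        rec = read_records(p, format="nightscout-json")
        assert [v for _, v in rec.records] == ["105", "108"]

    def test_unknown_format_and_empty_file(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("timestamp,glucose_mgdl\n")
        with pytest.raises(ValueError):
            read_records(p)
        with pytest.raises(ValueError):
            read_records(p, format="xml")


class TestClean:
    def test_duplicate_timestamp_keeps_first(self):
        raw = RawRecordSet([
            ("2021-01-01T00:00:00Z", "100"),
            ("2021-01-01T00:00:00Z", "200"),
            ("2021-01-01T00:05:00Z", "110"),
        ])
        series, log = clean(raw)
        assert list(series.values) == [100.0, 110.0]
        assert log.n_duplicates_dropped == 1

    def test_out_of_range_dropped(self):
        raw = RawRecordSet([
            ("2021-01-01T00:00:00Z", "600"),
            ("2021-01-01T00:05:00Z", "100"),
            ("2021-01-01T00:10:00Z", "110"),
        ])
        series, log = clean(raw)
        assert log.n_out_of_range_dropped == 1
        assert len(series) == 2

    def test_already_clean_is_identity(self):
        raw = RawRecordSet([
            ("2021-01-01T00:00:00Z", "100"),
            ("2021-01-01T00:05:00Z", "110"),
        ])
        series, log = clean(raw)
        assert log.n_duplicates_dropped == log.n_unparsable_dropped == log.n_out_of_range_dropped == 0
        assert list(series.values) == [100.0, 110.0]

    def test_conservation_of_records(self):
        raw = RawRecordSet([
            ("2021-01-01T00:00:00Z", "100"),
            ("2021-01-01T00:00:00Z", "100"),
            ("2021-01-01T00:05:00Z", "abc"),
            ("not a time", "100"),
            ("2021-01-01T00:10:00Z", "600"),
            ("2021-01-01T00:15:00Z", "120"),
            ("2021-01-01T00:20:00Z", "125"),
        ])
        series, log = clean(raw)
        assert log.n_input == 7
        assert log.n_kept == len(series) == 3
        assert (log.n_kept + log.n_duplicates_dropped + log.n_unparsable_dropped
                + log.n_out_of_range_dropped) == log.n_input

    def test_sorting(self):
        raw = RawRecordSet([
            ("2021-01-01T00:10:00Z", "120"),
            ("2021-01-01T00:00:00Z", "100"),
            ("2021-01-01T00:05:00Z", "110"),
        ])
        series, _ = clean(raw)
        assert list(series.values) == [100.0, 110.0, 120.0]

    def test_too_few_valid_records(self):
        with pytest.raises(ValueError, match="valid records"):
            clean(RawRecordSet([("2021-01-01T00:00:00Z", "100")]))

    def test_clean_is_idempotent(self):
        raw = RawRecordSet([
            ("2021-01-01T00:00:00Z", "100"),
            ("2021-01-01T00:00:00Z", "130"),
            ("2021-01-01T00:05:00Z", "abc"),
            ("2021-01-01T00:10:00Z", "120"),
        ])
        first, _ = clean(raw)
        rerun = RawRecordSet([
            (t.strftime("%Y-%m-%dT%H:%M:%SZ"), repr(float(v)))
            for t, v in zip(first.timestamps, first.values)
        ])
        second, log2 = clean(rerun)
        assert np.array_equal(first.values, second.values)
        assert log2.n_kept == log2.n_input


class TestResample:
    def test_gridded_input_is_identity(self):
        s = make_series([100, 110, 120, 130])
        out = resample_to_grid(s)
        assert np.array_equal(out.values, s.values)
        assert out.timestamps.equals(s.timestamps)

    def test_single_missing_slot_interpolated(self):
        s = make_series([100, 110, 120])
        gap = s.to_pandas().drop(s.timestamps[1])
        from glucovar.series import GlucoseSeries
        from glucovar.ingest import CleaningLog

        log = CleaningLog()
        out = resample_to_grid(GlucoseSeries.from_pandas(gap), log=log)
        assert out.values[1] == pytest.approx(110.0)  # midpoint of neighbours
        assert log.n_interpolated == 1

    def test_two_hour_gap_left_missing(self):
        vals = [100.0] * 6 + [120.0] * 6
        s = make_series(vals)
        ser = s.to_pandas()
        # remove 24 slots' worth by shifting second half 2 h later
        second = ser.iloc[6:]
        second.index = second.index + pd.Timedelta(hours=2)
        from glucovar.series import GlucoseSeries
        from glucovar.ingest import CleaningLog

        merged = pd.concat([ser.iloc[:6], second])
        log = CleaningLog()
        out = resample_to_grid(GlucoseSeries.from_pandas(merged), log=log)
        assert log.n_gap_slots == 24
        assert log.n_interpolated == 0
        assert np.isnan(out.values[6:30]).all()

    def test_offgrid_observation_snaps_to_nearest_slot(self):
        ts = pd.DatetimeIndex([
            "2021-01-01T00:00:00Z", "2021-01-01T00:05:40Z", "2021-01-01T00:10:00Z"
        ])
        from glucovar.series import GlucoseSeries

        s = GlucoseSeries(ts, np.array([100.0, 110.0, 120.0]))
        out = resample_to_grid(s)
        assert list(out.values) == [100.0, 110.0, 120.0]


class TestSplit:
    def test_lengths_and_adjacency(self):
        s = generate_trace(SimConfig(duration=32, seed=0))
        train, test = split_train_test(s, SplitSpec(30, 48))
        assert len(train) == 30 * 288
        assert len(test) == 576
        assert test.timestamps[0] - train.timestamps[-1] == pd.Timedelta(minutes=5)

    def test_insufficient_span_raises(self):
        s = generate_trace(SimConfig(duration=10, seed=0))
        with pytest.raises(ValueError, match="days"):
            split_train_test(s, SplitSpec(30, 48))

    def test_shorter_horizon(self):
        s = generate_trace(SimConfig(duration=31, seed=0))
        _, test = split_train_test(s, SplitSpec(30, 24))
        assert len(test) == 288


def test_round_trip_simulated_trace_survives_pipeline():
    s = generate_trace(SimConfig(duration=2, seed=42))
    rec = inject_artifacts(s, ArtifactConfig(seed=0))
    series, log = clean(rec)
    out = resample_to_grid(series, log=log)
    assert log.n_kept == log.n_input
    assert out.timestamps.equals(s.timestamps)
    assert np.allclose(out.values, s.values)
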