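"""AAMI mapping, record splits, experiment filters and WFDB round-trips."""

import hashlib

import numpy as np
import pytest

from pmat import wfdb_io
from pmat.datasets import (EXCLUDED_MITDB_RECORDS, apply_experiment_filters,
                           beats_table, build_split, map_aami,
                           prepare_database, read_record,
                           subsample_edb_normals)
from pmat.preprocessing import HeartbeatRecord, RRFeatures
from pmat.synthetic import RhythmSpec, synth_record, write_wfdb_fixture

SPLIT_HASHES = {
    "mitdb": "42d2404f9ecd1cd4",
    "incartdb": "68945841ea42ac77",
    "edb": "5248b502c3a3f31e",
}


def make_beat(label, record="100", database="mitdb", peak=1000):
    feats = RRFeatures(0.8, 0.8, 0.8, 1.0)
    return HeartbeatRecord(segment=np.zeros(10), image=np.zeros((120, 120)),
                           features=feats, label=label,
                           source=(database, record, peak))


class TestAAMIMapping:
    @pytest.mark.parametrize("symbol, expected", [
        ("N", "N"), ("L", "N"), ("R", "N"), ("e", "N"), ("j", "N"),
        ("A", "S"), ("a", "S"), ("J", "S"), ("S", "S"),
        ("V", "V"), ("E", "V"),
        ("F", "F"),
        ("/", "Q"), ("f", "Q"), ("Q", "Q"),
    ])
    def test_beat_symbols(self, symbol, expected):
        assert map_aami(symbol) == expected

    @pytest.mark.parametrize("symbol", ["+", "~", "|", '"', "[", "]", "x"])
    def test_non_beat_symbols_ignored(self, symbol):
        assert map_aami(symbol) is None

    def test_unknown_beat_symbol_maps_to_q_with_warning(self):
        with pytest.warns(UserWarning, match="unknown beat symbol"):
            assert map_aami("B") == "Q"

    def test_mapping_is_total_over_annotation_table(self):
        for symbol in wfdb_io.SYMBOL_TO_CODE:
            with pytest.warns(UserWarning) if symbol in ("B", "n", "r") else \
                    _nullcontext():
                result = map_aami(symbol)
            assert result in ("N", "S", "V", "F", "Q", None)


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


class TestSplits:
    @pytest.mark.parametrize("db, n_train, n_test", [
        ("mitdb", 22, 21), ("incartdb", 39, 36), ("edb", 0, 47)])
    def test_counts_and_disjointness(self, db, n_train, n_test):
        split = build_split(db)
        assert len(split.train_records) == n_train
        assert len(split.test_records) == n_test
        assert not set(split.train_records) & set(split.test_records)

    @pytest.mark.parametrize("db", ["mitdb", "incartdb", "edb"])
    def test_lists_are_pinned(self, db):
        split = build_split(db)
        blob = ",".join(split.train_records) + "|" + ",".join(
            split.test_records)
        assert hashlib.sha256(blob.encode()).hexdigest()[:16] == \
            SPLIT_HASHES[db]

    def test_membership_examples(self):
        mitdb = build_split("mitdb")
        assert "101" in mitdb.train_records
        assert "100" in mitdb.test_records
        assert not EXCLUDED_MITDB_RECORDS & set(mitdb.train_records)
        assert not EXCLUDED_MITDB_RECORDS & set(mitdb.test_records)

    def test_unknown_database_rejected(self):
        with pytest.raises(ValueError, match="unknown database"):
            build_split("ptbdb")


class TestExperimentFilters:
    def test_excluded_records_and_classes(self):
        beats = [make_beat("N", record="107"),
                 make_beat("V", record="217"),
                 make_beat("F"), make_beat("Q"),
                 make_beat("N"), make_beat("S"), make_beat("V")]
        kept, ledger = apply_experiment_filters(beats, "mitdb")
        assert [b.label for b in kept] == ["N", "S", "V"]
        assert ledger == {"excluded-record": 2, "class-Q": 1, "class-F": 1}
        assert len(kept) + sum(ledger.values()) == len(beats)

    def test_record_exclusion_is_mitdb_only(self):
        beats = [make_beat("N", record="107", database="incartdb")]
        kept, ledger = apply_experiment_filters(beats, "incartdb")
        assert len(kept) == 1 and ledger["excluded-record"] == 0


class TestEdbSubsampling:
    def _beats(self, n_normals, record="e0103"):
        return [make_beat("N", record=record, database="edb", peak=i)
                for i in range(n_normals)]

    def test_caps_normals_per_record(self):
        beats = self._beats(2000) + [make_beat("S", database="edb"),
                                     make_beat("V", database="edb")]
        kept = subsample_edb_normals(beats, per_record=500, seed=1)
        labels = [b.label for b in kept]
        assert labels.count("N") == 500
        assert labels.count("S") == 1 and labels.count("V") == 1

    def test_small_records_kept_whole(self):
        kept = subsample_edb_normals(self._beats(300), per_record=500, seed=1)
        assert len(kept) == 300

    def test_seed_determinism(self):
        beats = self._beats(800)
        first = subsample_edb_normals(beats, 500, seed=9)
        second = subsample_edb_normals(beats, 500, seed=9)
        assert [b.source for b in first] == [b.source for b in second]


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    directory = tmp_path_factory.mktemp("wfdb")
    spec = RhythmSpec(n_beats=30, seed=21)
    record, labels = synth_record(spec)
    write_wfdb_fixture(record, labels, directory, name="synth")
    return directory, record, labels


class TestWFDBRoundTrip:
    def test_samples_and_peaks_round_trip(self, fixture_dir):
        directory, record, labels = fixture_dir
        loaded = read_record(directory / "synth")
        assert loaded.sampling_rate == record.sampling_rate
        np.testing.assert_array_equal(loaded.r_peaks, record.r_peaks)
        span = record.samples.max() - record.samples.min()
        assert np.abs(loaded.samples - record.samples).max() < 1e-3 * span

    def test_labels_round_trip_through_aami(self, fixture_dir):
        directory, _, labels = fixture_dir
        loaded = read_record(directory / "synth")
        assert [map_aami(s) for s in loaded.beat_symbols] == labels

    def test_missing_lead_is_reported(self, fixture_dir):
        directory, record, labels = fixture_dir
        wfdb_io.write_record(directory, "v5only", record.samples[:2000],
                             record.sampling_rate, annotations=[(100, "N")],
                             lead_names=("V5",))
        with pytest.raises(LookupError, match="lead-missing"):
            read_record(directory / "v5only")

    def test_format_212_decoding(self, tmp_path):
        # pack two known 12-bit samples per 3 bytes by hand (independent
        # of the reader) and check the decoder recovers them
        adc = np.array([[100, -100], [2047, -2048], [0, 1]], dtype=int)
        raw = bytearray()
        for s0, s1 in adc:
            u0, u1 = s0 & 0xFFF, s1 & 0xFFF
            raw += bytes([u0 & 0xFF, (u0 >> 8) | ((u1 >> 8) << 4),
                          u1 & 0xFF])
        (tmp_path / "r212.dat").write_bytes(bytes(raw))
        (tmp_path / "r212.hea").write_text(
            "r212 2 360 3\nr212.dat 212 200(0)/mV 12 0 100 0 0 MLII\n"
            "r212.dat 212 200(0)/mV 12 0 -100 0 0 V1\n")
        header = wfdb_io.read_header(tmp_path / "r212.hea")
        signals = wfdb_io.read_signals(header, tmp_path)
        np.testing.assert_allclose(signals * 200, adc)

    def test_skip_annotation_for_long_gaps(self, tmp_path):
        annotations = [(500, "N"), (200_000, "V"), (200_360, "A")]
        wfdb_io.write_annotations(tmp_path / "gap.atr", annotations)
        assert wfdb_io.read_annotations(tmp_path / "gap.atr") == annotations


class TestPrepareDatabase:
    def test_counts_conserved_and_exclusions_applied(self, tmp_path):
        spec = RhythmSpec(n_beats=40, seed=5)
        record, labels = synth_record(spec)
        write_wfdb_fixture(record, labels, tmp_path, name="100")
        write_wfdb_fixture(record, labels, tmp_path, name="107")
        beats, ledger = prepare_database(tmp_path, "mitdb",
                                         records=["100", "107"])
        # record 107 contributes nothing; boundary beats excluded
        assert {b.source[1] for b in beats} == {"100"}
        assert ledger["excluded-record-skipped"] == 1
        assert len(beats) + ledger["missing-neighbor"] == len(labels)
        table = beats_table(beats)
        assert set(table.columns) == {"database", "record", "peak_sample",
                                      "pre_rr", "post_rr", "local_rr",
                                      "ratio_rr", "label"}
        assert (table["label"].isin(["N", "S", "V"])).all()
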