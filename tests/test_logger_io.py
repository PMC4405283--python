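"""Parsing, filtering, reciprocal compression and onset tie-breaking."""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as st

from triadrem import logger_io
from triadrem.logger_io import (
    DYADS,
    ContactInterval,
    ContactRecord,
    LoggerParseError,
    LoggerValidationError,
    ParseReport,
    TriadManifest,
    break_onset_ties,
    compress_reciprocal,
    filter_short_contacts,
    parse_logger_file,
)


class TestParse:
    def test_durations_recomputed_from_timestamps(self, sample_text, manifest):
        records = parse_logger_file(sample_text, manifest)
        assert [r.duration_s for r in records] == [1, 183, 16, 110, 16, 3]
        # the 183 s contact spans 18:52:57 -> 18:56:00
        long = records[1]
        assert long.start == datetime(2009, 3, 9, 18, 52, 57)
        assert (long.end - long.start).total_seconds() == 183

    def test_empty_source_gives_empty_collection(self, manifest):
        assert parse_logger_file("", manifest) == []

    def test_end_before_start_is_a_validation_error(self, manifest):
        bad = (
            "Cow ID,Encountered cow ID,Start date,Start time,End date,End time,Duration (seconds)\n"
            "1,2,9/03/2009,18:52:57,9/03/2009,18:50:00,183\n"
        )
        with pytest.raises(LoggerValidationError, match="row 2"):
            parse_logger_file(bad, manifest)

    def test_duration_column_mismatch_names_the_row(self, manifest):
        bad = (
            "Cow ID,Encountered cow ID,Start date,Start time,End date,End time,Duration (seconds)\n"
            "1,2,9/03/2009,18:52:57,9/03/2009,18:56:00,999\n"
        )
        with pytest.raises(LoggerValidationError, match="row 2"):
            parse_logger_file(bad, manifest)

    def test_malformed_timestamp_names_the_row(self, manifest):
        bad = (
            "Cow ID,Encountered cow ID,Start date,Start time,End date,End time,Duration (seconds)\n"
            "1,2,not-a-date,18:52:57,9/03/2009,18:56:00,183\n"
        )
        with pytest.raises(LoggerParseError, match="row 2"):
            parse_logger_file(bad, manifest)

    def test_unknown_animals_are_rejected_with_report(self, manifest):
        text = (
            "Cow ID,Encountered cow ID,Start date,Start time,End date,End time,Duration (seconds)\n"
            "1,2,9/03/2009,18:52:57,9/03/2009,18:56:00,183\n"
            "1,99,9/03/2009,18:52:57,9/03/2009,18:56:00,183\n"
        )
        report = ParseReport()
        records = parse_logger_file(text, manifest, report=report)
        assert len(records) == 1
        assert len(report.rejected) == 1 and report.rejected[0][0] == 3

    def test_tab_delimited_auto_detected(self, sample_text, manifest):
        tabbed = sample_text.replace(",", "\t")
        assert parse_logger_file(tabbed, manifest) == parse_logger_file(
            sample_text, manifest
        )

    def test_dayfirst_dates(self, manifest):
        text = (
            "Cow ID,Encountered cow ID,Start date,Start time,End date,End time,Duration (seconds)\n"
            "1,2,9/03/2009,18:52:57,9/03/2009,18:56:00,183\n"
        )
        (rec,) = parse_logger_file(text, manifest)
        assert (rec.start.day, rec.start.month) == (9, 3)


class TestFilter:
    def test_minimum_two_seconds_on_sample(self, sample_text, manifest):
        records = parse_logger_file(sample_text, manifest)
        kept = filter_short_contacts(records)
        assert len(kept) == 5
        assert [r.duration_s for r in kept] == [183, 16, 110, 16, 3]

    def test_exactly_minimum_is_retained(self, manifest):
        rec = ContactRecord(
            "1", "2",
            datetime(2009, 3, 9, 10, 0, 0), datetime(2009, 3, 9, 10, 0, 2), 2,
        )
        assert filter_short_contacts([rec]) == [rec]

    def test_all_short_gives_empty(self, sample_text, manifest):
        records = parse_logger_file(sample_text, manifest)
        assert filter_short_contacts(records, min_duration_s=1000) == []

    def test_order_preserved(self, sample_text, manifest):
        records = parse_logger_file(sample_text, manifest)
        kept = filter_short_contacts(records)
        assert kept == [r for r in records if r.duration_s >= 2]


def _rec(manifest, a, b, start_s, end_s):
    t0 = manifest.introduction
    return ContactRecord(
        a, b,
        t0 + timedelta(seconds=start_s), t0 + timedelta(seconds=end_s),
        end_s - start_s,
    )


class TestCompressReciprocal:
    def test_duplicate_reports_become_one_interval(self, plain_manifest):
        recs = [
            _rec(plain_manifest, "a", "b", 100, 200),
            _rec(plain_manifest, "b", "a", 100, 200),
        ]
        out = compress_reciprocal(recs, plain_manifest)
        assert out[(1, 2)] == [ContactInterval((1, 2), 100, 200)]

    def test_overlapping_intervals_merge(self, plain_manifest):
        recs = [
            _rec(plain_manifest, "a", "b", 100, 200),
            _rec(plain_manifest, "b", "a", 150, 300),
        ]
        out = compress_reciprocal(recs, plain_manifest)
        assert out[(1, 2)] == [ContactInterval((1, 2), 100, 300)]

    def test_disjoint_intervals_stay_disjoint(self, plain_manifest):
        recs = [
            _rec(plain_manifest, "a", "b", 100, 200),
            _rec(plain_manifest, "a", "b", 300, 400),
        ]
        out = compress_reciprocal(recs, plain_manifest)
        assert [(iv.onset_t, iv.offset_t) for iv in out[(1, 2)]] == [
            (100, 200), (300, 400),
        ]

    def test_pre_introduction_records_dropped_and_straddlers_clipped(self):
        m = TriadManifest(
            "t", {"a": 1, "b": 2, "c": 3}, datetime(2009, 3, 9, 12, 0, 0)
        )
        before = _rec(m, "a", "b", -100, -10)
        straddle = _rec(m, "a", "c", -50, 60)
        out = compress_reciprocal([before, straddle], m)
        assert out[(1, 2)] == []
        assert out[(1, 3)] == [ContactInterval((1, 3), 0, 60)]

    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=12
        )
    )
    def test_union_coverage_and_idempotence(self, spans):
        """Merged output covers exactly the union of input seconds and is
        already maximally merged."""
        m = TriadManifest("t", {"a": 1, "b": 2, "c": 3}, datetime(2009, 3, 9))
        recs = [_rec(m, "a", "b", s, s + w) for s, w in spans]
        out = compress_reciprocal(recs, m)[(1, 2)]
        covered = set()
        for iv in out:
            covered.update(range(iv.onset_t, iv.offset_t))
        expected = set()
        for s, w in spans:
            expected.update(range(s, s + w))
        assert covered == expected
        # maximal: strictly separated intervals (no overlap, no abutting)
        for a, b in zip(out, out[1:]):
            assert b.onset_t > a.offset_t


class TestBreakOnsetTies:
    def test_two_coinciding_onsets_shift_by_dyad_order(self, intervals_factory):
        ivs = intervals_factory({(1, 2): [(500, 600)], (1, 3): [(500, 700)]})
        out = break_onset_ties(ivs)
        assert out[(1, 2)][0].onset_t == 500
        assert out[(1, 3)][0].onset_t == 501

    def test_no_coinciding_onsets_unchanged(self, intervals_factory):
        ivs = intervals_factory({(1, 2): [(100, 200)], (2, 3): [(300, 400)]})
        out = break_onset_ties(ivs)
        assert out == ivs

    def test_three_coinciding_onsets_shift_0_1_2(self, intervals_factory):
        ivs = intervals_factory(
            {(1, 2): [(500, 900)], (1, 3): [(500, 900)], (2, 3): [(500, 900)]}
        )
        out = break_onset_ties(ivs)
        assert [out[d][0].onset_t for d in DYADS] == [500, 501, 502]
        assert [out[d][0].offset_t for d in DYADS] == [900, 900, 900]

    def test_offset_moves_only_to_keep_interval_nonempty(self, intervals_factory):
        ivs = intervals_factory({(1, 2): [(500, 501)], (1, 3): [(500, 501)]})
        out = break_onset_ties(ivs)
        iv = out[(1, 3)][0]
        assert (iv.onset_t, iv.offset_t) == (501, 502)

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(DYADS), st.integers(0, 50), st.integers(1, 30)
            ),
            max_size=15,
        )
    )
    def test_onsets_globally_distinct_and_per_dyad_increasing(self, data):
        per_dyad: dict = {d: [] for d in DYADS}
        cursor = {d: 0 for d in DYADS}
        for dyad, gap, width in data:
            s = cursor[dyad] + gap
            per_dyad[dyad].append(ContactInterval(dyad, s, s + width))
            cursor[dyad] = s + width + 1  # keep per-dyad intervals separated
        out = break_onset_ties(per_dyad)
        onsets = [iv.onset_t for d in DYADS for iv in out[d]]
        assert len(onsets) == len(set(onsets))
        for d in DYADS:
            ts = [iv.onset_t for iv in out[d]]
            assert ts == sorted(ts)
            assert len(ts) == len(set(ts))
            for iv in out[d]:
                assert iv.offset_t > iv.onset_t


class TestRoundTrip:
    def test_intervals_to_logger_text_and_back(self, plain_manifest):
        ivs = {
            (1, 2): [ContactInterval((1, 2), 10, 50), ContactInterval((1, 2), 80, 90)],
            (1, 3): [ContactInterval((1, 3), 20, 45)],
            (2, 3): [],
        }
        recs = logger_io.intervals_to_records(ivs, plain_manifest)
        text = logger_io.write_logger_text(recs)
        reparsed = parse_logger_file(text, plain_manifest)
        assert compress_reciprocal(reparsed, plain_manifest) == ivs

    def test_interval_file_round_trip(self, tmp_path):
        ivs = {
            (1, 2): [ContactInterval((1, 2), 0, 5)],
            (1, 3): [],
            (2, 3): [ContactInterval((2, 3), 7, 11)],
        }
        path = tmp_path / "intervals.tsv"
        logger_io.write_intervals(ivs, "t1", path)
        assert logger_io.read_intervals(path) == ivs

    def test_manifest_round_trip(self, tmp_path, manifest):
        path = tmp_path / "m.yaml"
        logger_io.write_manifest(manifest, path)
        back = logger_io.read_manifest(path)
        assert back == manifest
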