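"""Annotation/clip/R-R file reading, validation and visibility filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import EVENT_SORT_KEY, random_events
from facs_affect.events_io import (
    AnnotationEvent,
    ClipRecord,
    EventFileError,
    RRSeries,
    drop_unscorable,
    read_clips,
    read_events,
    read_hrm,
    validate_dataset,
    write_clips,
    write_events,
    write_hrm,
)


def write_text(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEvents:
    def test_single_row_parsed_with_duration(self, tmp_path):
        p = write_text(tmp_path, "e.csv", "video_id,code,onset,offset\nv1,AD38,1.50,3.25\n")
        events = read_events(p)
        assert events == [AnnotationEvent("v1", "AD38", 1.5, 3.25)]
        assert events[0].duration == pytest.approx(1.75)

    def test_header_only_gives_empty_list(self, tmp_path):
        p = write_text(tmp_path, "e.csv", "video_id,code,onset,offset\n")
        assert read_events(p) == []

    def test_rows_out_of_order_returned_sorted(self, tmp_path, rng):
        events = random_events(rng, 40, codes=("AD38", "AU145", "AD19"))
        shuffled = list(events)
        rng.shuffle(shuffled)
        lines = ["video_id,code,onset,offset"] + [
            f"{e.video_id},{e.code},{e.onset},{e.offset}" for e in shuffled
        ]
        p = write_text(tmp_path, "e.csv", "\n".join(lines) + "\n")
        got = read_events(p)
        # oracle: naive parse then sort; content identical to the input set
        assert got == sorted(shuffled, key=EVENT_SORT_KEY)
        assert sorted(got, key=EVENT_SORT_KEY) == sorted(events, key=EVENT_SORT_KEY)

    def test_unknown_code_rejected_unless_lax(self, tmp_path):
        p = write_text(tmp_path, "e.csv", "video_id,code,onset,offset\nv1,AU999,0,1\n")
        with pytest.raises(EventFileError, match="AU999"):
            read_events(p)
        with pytest.warns(UserWarning, match="AU999"):
            assert len(read_events(p, lax=True)) == 1

    def test_errors_name_line_number(self, tmp_path):
        p = write_text(
            tmp_path, "e.csv",
            "video_id,code,onset,offset\nv1,AD38,0,1\nv1,AD38,5,2\n",
        )
        with pytest.raises(EventFileError, match=":3:"):
            read_events(p)
        p2 = write_text(tmp_path, "e2.csv", "video_id,code,onset,offset\nv1,AD38,x,1\n")
        with pytest.raises(EventFileError, match=":2:.*non-numeric"):
            read_events(p2)

    def test_round_trip_preserves_event_multiset(self, tmp_path, rng):
        events = random_events(rng, 60)
        p = tmp_path / "rt.csv"
        write_events(events, p)
        assert read_events(p) == events

    def test_zero_duration_event_allowed(self, tmp_path):
        p = write_text(tmp_path, "e.csv", "video_id,code,onset,offset\nv1,AU145,2.0,2.0\n")
        (e,) = read_events(p)
        assert e.duration == 0.0


class TestClips:
    def test_round_trip_and_validation(self, tmp_path):
        clips = [
            ClipRecord("v1", "h1", "PRI", "baseline", 100.0, 30.0),
            ClipRecord("v2", "h1", "PRI", "transportation", 400.0, 30.0),
        ]
        p = tmp_path / "c.csv"
        write_clips(clips, p)
        assert read_clips(p) == clips
        validate_dataset([AnnotationEvent("v1", "AD38", 0, 1)], clips)
        with pytest.raises(EventFileError, match="unknown video_id"):
            validate_dataset([AnnotationEvent("vX", "AD38", 0, 1)], clips)

    def test_duplicate_video_id_rejected(self, tmp_path):
        p = write_text(
            tmp_path, "c.csv",
            "video_id,horse_id,group,condition,clip_start,clip_length\n"
            "v1,h1,PRI,baseline,0,30\nv1,h2,PRI,baseline,0,30\n",
        )
        with pytest.raises(EventFileError, match="duplicate"):
            read_clips(p)

    def test_bad_group_or_condition_rejected(self):
        with pytest.raises(ValueError, match="group"):
            ClipRecord("v", "h", "ZOO", "baseline")
        with pytest.raises(ValueError, match="condition"):
            ClipRecord("v", "h", "PRI", "sleeping")


class TestRRFiles:
    def test_hrm_sections_parsed(self, tmp_path):
        p = write_text(
            tmp_path, "s.hrm",
            "[Params]\nVersion=106\nStartTime=0:00:00.0\n\n[HRData]\n1000\n1000\n1000\n",
        )
        s = read_hrm(p)
        assert list(s.rr) == [1000, 1000, 1000]
        assert list(s.beat_times) == [1.0, 2.0, 3.0]

    def test_csv_fallback(self, tmp_path):
        p = write_text(tmp_path, "s.csv", "beat_time_s,rr_ms\n0.8,800\n")
        s = read_hrm(p)
        assert list(s.rr) == [800.0]
        assert s.beat_times[0] == pytest.approx(0.8)

    def test_hrm_round_trip(self, tmp_path, rng):
        rr = rng.integers(600, 1400, size=10).astype(float)
        s = RRSeries("sess", "h1", "baseline", t0=3723.5, rr=rr)
        p = tmp_path / "sess.hrm"
        write_hrm(s, p)
        back = read_hrm(p, horse_id="h1", condition="baseline")
        assert np.array_equal(back.rr, rr)
        assert back.t0 == pytest.approx(3723.5)
        assert back.session_id == "sess"

    def test_missing_data_section_errors(self, tmp_path):
        p = write_text(tmp_path, "bad.hrm", "[Params]\nVersion=106\n")
        with pytest.raises(EventFileError, match="HRData"):
            read_hrm(p)

    def test_non_positive_interval_errors(self, tmp_path):
        p = write_text(tmp_path, "bad.hrm", "[HRData]\n1000\n0\n")
        with pytest.raises(EventFileError, match="non-positive"):
            read_hrm(p)


class TestDropUnscorable:
    def test_fully_covered_event_removed(self):
        events = [
            AnnotationEvent("v", "VC74", 0, 5),
            AnnotationEvent("v", "AU145", 1, 2),
        ]
        assert drop_unscorable(events) == []

    def test_partial_overlap_kept_untrimmed(self):
        events = [
            AnnotationEvent("v", "VC74", 0, 5),
            AnnotationEvent("v", "AD38", 4, 7),
        ]
        assert drop_unscorable(events) == [AnnotationEvent("v", "AD38", 4, 7)]

    def test_no_vc74_is_identity(self, rng):
        events = random_events(rng, 30)
        assert drop_unscorable(events) == events

    def test_matches_containment_oracle(self, rng):
        events = []
        for vid in ("a", "b"):
            events += random_events(rng, 40, video=vid)
            for _ in range(3):
                on = float(rng.uniform(0, 25))
                events.append(AnnotationEvent(vid, "VC74", on, on + float(rng.uniform(1, 8))))
        got = drop_unscorable(events)
        vc = [e for e in events if e.code == "VC74"]
        expected = [
            e for e in events
            if e.code != "VC74"
            and not any(
                v.video_id == e.video_id and v.onset <= e.onset and e.offset <= v.offset
                for v in vc
            )
        ]
        assert got == expected


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["AD38", "AU145", "AD19"]),
            st.floats(min_value=0, max_value=30, allow_nan=False),
            st.floats(min_value=0, max_value=5, allow_nan=False),
        ),
        max_size=25,
    )
)
def test_read_events_permutation_invariant(tmp_path_factory, rows):
    """Reading is invariant to the order of input rows."""
    tmp = tmp_path_factory.mktemp("perm")
    events = [AnnotationEvent("v1", c, on, on + d) for c, on, d in rows]
    p1, p2 = tmp / "a.csv", tmp / "b.csv"
    write_events(events, p1)
    write_events(events[::-1], p2)
    assert read_events(p1) == read_events(p2)
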