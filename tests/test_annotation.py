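import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from surgevents import (
    LabelEvent,
    LabelSchema,
    aggregate_label_counts,
    build_intervals,
    default_schema,
    extract_clips,
    parse_labels,
)
from surgevents.annotation import serialize_labels
from surgevents.exceptions import PairingError, ParseError, ValidationError
from surgevents.synthio import generate_label_file

from .oracles import pair_start_stop


def write_tsv(path, rows, header="Time\tBehavior\tStatus"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

def test_default_schema_shape():
    schema = default_schema()
    assert len(schema.categories["suturing"]) == 4
    assert len(schema.categories["dissection"]) == 3
    assert len(schema.categories["other"]) == 8
    assert "Suture puncture" in schema
    assert schema.category_of("Dissection, clips") == "dissection"


def test_schema_rejects_duplicate_subcategories():
    with pytest.raises(ValidationError):
        LabelSchema({"a": ["x"], "b": ["x"]})


def test_schema_yaml_round_trip(tmp_path):
    schema = default_schema()
    schema.to_yaml(tmp_path / "s.yaml")
    loaded = LabelSchema.from_yaml(tmp_path / "s.yaml")
    assert loaded.categories == schema.categories


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_two_row_file(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv", [
        "10.0\tDissection, ordinary\tSTART",
        "25.0\tDissection, ordinary\tSTOP",
    ])
    events = parse_labels(tsv)
    assert events == [
        LabelEvent(10.0, "Dissection, ordinary", "START"),
        LabelEvent(25.0, "Dissection, ordinary", "STOP"),
    ]


def test_parse_missing_status_column_is_error(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv", ["1.0\tSuction"],
                    header="Time\tBehavior")
    with pytest.raises(ParseError, match="status"):
        parse_labels(tsv)


def test_parse_case_insensitive_headers_and_extra_columns(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv",
                    ["obs1\t10.5\tSuction\tpoint\tSTART",
                     "obs1\t11.5\tSuction\tpoint\tSTOP"],
                    header="Observation\tTIME\tbehavior\tModifier\tStatus")
    events = parse_labels(tsv)
    assert [e.behavior for e in events] == ["Suction", "Suction"]
    assert [e.time_s for e in events] == [10.5, 11.5]


def test_parse_schema_accepts_table_behaviors(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv", [
        "1.0\tSuture puncture\tSTART",
        "2.0\tSuture puncture\tSTOP",
    ])
    assert len(parse_labels(tsv)) == 2


def test_parse_unknown_behavior_is_error_unless_unenforced(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv", [
        "1.0\tJuggling\tSTART",
        "2.0\tJuggling\tSTOP",
    ])
    with pytest.raises(ParseError, match="Juggling"):
        parse_labels(tsv)
    assert len(parse_labels(tsv, enforce_schema=False)) == 2


def test_parse_unparseable_time_reports_line(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv", [
        "1.0\tSuction\tSTART",
        "oops\tSuction\tSTOP",
    ])
    with pytest.raises(ParseError, match="line 3"):
        parse_labels(tsv)


def test_parse_sorts_by_time_keeping_file_order_on_ties(tmp_path):
    tsv = write_tsv(tmp_path / "l.tsv", [
        "5.0\tSuction\tSTOP",
        "1.0\tSuction\tSTART",
        "5.0\tCleaning\tSTART",
        "6.0\tCleaning\tSTOP",
    ])
    events = parse_labels(tsv)
    assert [e.time_s for e in events] == [1.0, 5.0, 5.0, 6.0]
    assert events[1].behavior == "Suction"  # file order preserved at t=5.0


def test_serialize_parse_round_trip(tmp_path):
    events, _ = generate_label_file(
        {"Suction": 5, "Cleaning": 3, "Suture puncture": 4},
        duration_s=600.0, seed=12)
    path = tmp_path / "out.tsv"
    serialize_labels(events, path)
    assert parse_labels(path) == events


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def test_single_interval():
    intervals = build_intervals([
        LabelEvent(10.0, "Dissection, ordinary", "START"),
        LabelEvent(25.0, "Dissection, ordinary", "STOP"),
    ])
    assert len(intervals) == 1
    iv = intervals[0]
    assert (iv.start_s, iv.stop_s, iv.duration_s) == (10.0, 25.0, 15.0)


def test_interleaved_behaviors_pair_independently():
    events = [
        LabelEvent(0.0, "Suction", "START"),
        LabelEvent(5.0, "Cleaning", "START"),
        LabelEvent(8.0, "Suction", "STOP"),
        LabelEvent(9.0, "Cleaning", "STOP"),
    ]
    intervals = build_intervals(events)
    spans = {(iv.behavior, iv.start_s, iv.stop_s) for iv in intervals}
    assert spans == {("Suction", 0.0, 8.0), ("Cleaning", 5.0, 9.0)}


def test_stop_without_start_is_pairing_error():
    with pytest.raises(PairingError):
        build_intervals([LabelEvent(3.0, "Suction", "STOP")])


def test_unclosed_start_names_behavior():
    with pytest.raises(PairingError, match="Suction"):
        build_intervals([LabelEvent(3.0, "Suction", "START")])


def test_strict_mode_rejects_nested_same_behavior():
    events = [
        LabelEvent(0.0, "Suction", "START"),
        LabelEvent(1.0, "Suction", "START"),
        LabelEvent(2.0, "Suction", "STOP"),
        LabelEvent(3.0, "Suction", "STOP"),
    ]
    assert len(build_intervals(events)) == 2  # permissive default: LIFO nesting
    with pytest.raises(PairingError):
        build_intervals(events, strict=True)


@given(st.integers(0, 2 ** 31 - 1))
def test_pairing_agrees_with_bruteforce_matcher(seed):
    rng = np.random.default_rng(seed)
    behaviors = ["Suction", "Cleaning", "Suture puncture"]
    events, t = [], 0.0
    open_count = {b: 0 for b in behaviors}
    for _ in range(30):
        t += float(rng.uniform(0.1, 2.0))
        b = behaviors[rng.integers(0, len(behaviors))]
        if open_count[b] > 0 and rng.random() < 0.5:
            events.append(LabelEvent(t, b, "STOP"))
            open_count[b] -= 1
        else:
            events.append(LabelEvent(t, b, "START"))
            open_count[b] += 1
    for b, n in open_count.items():
        for _ in range(n):
            t += 1.0
            events.append(LabelEvent(t, b, "STOP"))

    got = [(iv.behavior, iv.start_s, iv.stop_s) for iv in build_intervals(events)]
    expected = pair_start_stop([(e.time_s, e.behavior, e.status) for e in events])
    assert got == expected


def test_interval_count_equals_start_count(tmp_path):
    events, _ = generate_label_file({"Suction": 7, "Cleaning": 2},
                                    duration_s=300.0, seed=5)
    n_starts = sum(1 for e in events if e.status == "START")
    assert len(build_intervals(events)) == n_starts == 9


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_category_totals_equal_subcategory_sums():
    suturing = {"Suture puncture": 412, "Suture handling": 570,
                "Suture, single": 13, "Suture, running": 37}
    dissection = {"Dissection, ordinary": 769, "Dissection, clips": 125,
                  "Dissection hemostasis": 82}
    events, _ = generate_label_file({**suturing, **dissection},
                                    duration_s=86820.0, seed=1)
    table = aggregate_label_counts([events])
    assert table.category_totals["suturing"] == 1032
    assert table.category_totals["dissection"] == 976
    assert table.subcategory_counts["Dissection hemostasis"] == 82
    for cat, subs in table.schema.categories.items():
        assert table.category_totals[cat] == sum(
            table.subcategory_counts[s] for s in subs)


def test_aggregate_sums_across_files(tmp_path):
    p1 = tmp_path / "a.tsv"
    p2 = tmp_path / "b.tsv"
    generate_label_file({"Suction": 3}, duration_s=60.0, seed=1, out_path=p1)
    generate_label_file({"Suction": 4, "Cleaning": 2}, duration_s=60.0,
                        seed=2, out_path=p2)
    table = aggregate_label_counts([p1, p2])
    assert table.subcategory_counts["Suction"] == 7
    assert table.subcategory_counts["Cleaning"] == 2
    assert table.category_totals["other"] == 9


def test_aggregate_empty_input_all_zero():
    table = aggregate_label_counts([])
    assert table.total == 0
    assert set(table.category_totals.values()) == {0}


# ---------------------------------------------------------------------------
# clip extraction
# ---------------------------------------------------------------------------

def test_extract_clip_frame_arithmetic(tmp_path, rng):
    from surgevents import LabelInterval, read_video, write_video

    frames = rng.integers(0, 256, size=(450, 20, 30, 3), dtype=np.uint8)
    video = tmp_path / "v.tif"
    write_video(video, frames, fps=15.0)
    clips = extract_clips(video, [LabelInterval("Suction", 10.0, 25.0)],
                          tmp_path / "clips")
    assert len(clips) == 1
    clip_frames, fps = read_video(clips[0])
    assert clip_frames.shape[0] == 225  # frames 150..374 inclusive
    assert fps == 15.0
    np.testing.assert_array_equal(clip_frames, frames[150:375])


def test_extract_full_duration_clip_keeps_all_frames(tmp_path, rng):
    from surgevents import LabelInterval, read_video, write_video

    frames = rng.integers(0, 256, size=(45, 16, 16, 3), dtype=np.uint8)
    video = tmp_path / "v.tif"
    write_video(video, frames, fps=15.0)
    clips = extract_clips(video, [LabelInterval("Suction", 0.0, 3.0)],
                          tmp_path / "clips")
    clip_frames, _ = read_video(clips[0])
    assert clip_frames.shape[0] == 45


def test_extract_no_intervals_no_files(tmp_path, rng):
    from surgevents import write_video

    video = tmp_path / "v.tif"
    write_video(video, rng.integers(0, 256, (5, 8, 8, 3), dtype=np.uint8), 15.0)
    assert extract_clips(video, [], tmp_path / "clips") == []
    assert not list((tmp_path / "clips").glob("*"))


def test_extract_interval_beyond_duration_is_error(tmp_path, rng):
    from surgevents import LabelInterval, write_video
    from surgevents.exceptions import ParameterError

    video = tmp_path / "v.tif"
    write_video(video, rng.integers(0, 256, (30, 8, 8, 3), dtype=np.uint8), 15.0)
    with pytest.raises(ParameterError, match="exceeds"):
        extract_clips(video, [LabelInterval("Suction", 1.0, 10.0)],
                      tmp_path / "clips")
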