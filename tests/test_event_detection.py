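import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from surgevents import (
    EventChannel,
    State,
    detect_events,
    events_from_states,
    match_roi,
    normalized_correlation,
    scan_video,
)
from surgevents.exceptions import GeometryError, ParameterError
from surgevents.synthio import SyntheticScene, generate_console_video, random_timeline

from .oracles import debounced_runs, maximal_active_runs


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _frame_with(profile, channel, template, seed=0):
    rng = np.random.default_rng(seed)
    h, w = profile.frame_height, profile.frame_width
    frame = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    spec = profile.indicator(channel)
    roi = spec.roi
    frame[roi.y:roi.y + roi.h, roi.x:roi.x + roi.w] = template
    return frame, spec


def test_self_match_scores_exactly_one(toy_xi):
    frame, spec = _frame_with(toy_xi, EventChannel.COAG_R,
                              toy_xi.indicator(EventChannel.COAG_R).active_template)
    result = match_roi(frame, spec)
    assert result.score == 1.0
    assert result.state is State.ACTIVE


def test_noise_roi_is_inactive_and_matches_independent_correlation(toy_xi):
    """Random noise in the ROI scores far below threshold; the score agrees
    with scikit-image's match_template, an independent NCC implementation."""
    from skimage.feature import match_template

    spec = toy_xi.indicator(EventChannel.COAG_R)
    rng = np.random.default_rng(99)
    crop = rng.integers(0, 256, size=spec.active_template.shape, dtype=np.uint8)
    frame, _ = _frame_with(toy_xi, EventChannel.COAG_R, crop, seed=99)
    result = match_roi(frame, spec)
    assert result.state is State.INACTIVE
    assert result.score < 0.95

    reference = match_template(
        crop.astype(np.float64), spec.active_template.astype(np.float64)
    ).item()
    assert result.score == pytest.approx(reference, abs=1e-9)


def test_hover_template_match_reports_hover(toy_xi):
    spec = toy_xi.indicator(EventChannel.COAG_R)
    frame, _ = _frame_with(toy_xi, EventChannel.COAG_R, spec.hover_template)
    assert match_roi(frame, spec).state is State.HOVER


def test_flat_roi_does_not_match_flat_template_of_other_shade():
    from surgevents import IndicatorSpec, ROISpec

    spec = IndicatorSpec(
        channel=EventChannel.CAMERA,
        roi=ROISpec(x=0, y=0, w=4, h=4),
        active_template=np.full((4, 4, 3), 200, np.uint8),
    )
    frame = np.full((8, 8, 3), 100, np.uint8)
    assert match_roi(frame, spec).state is State.INACTIVE
    frame[:4, :4] = 200
    assert match_roi(frame, spec).state is State.ACTIVE


def test_roi_partially_outside_frame_is_geometry_error(toy_xi):
    spec = toy_xi.indicator(EventChannel.CAMERA)
    small = np.zeros((10, 10, 3), np.uint8)
    with pytest.raises(GeometryError):
        match_roi(small, spec)


def test_correlation_of_mismatched_sizes_is_geometry_error():
    with pytest.raises(GeometryError):
        normalized_correlation(np.zeros(4), np.zeros(5))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_scan_blank_video_all_inactive(toy_xi, rng):
    frames = rng.integers(0, 256, size=(10, 180, 320, 3), dtype=np.uint8)
    states = scan_video(frames, toy_xi)
    assert set(states) == set(toy_xi.channels)
    for seq in states.values():
        assert seq.shape == (10,)
        assert (seq == State.INACTIVE).all()


def test_scan_recovers_scripted_active_frames(toy_xi):
    tl = random_timeline(toy_xi, duration_s=4, seed=11)
    frames, _ = generate_console_video(tl, toy_xi, SyntheticScene(seed=4))
    states = scan_video(frames, toy_xi)
    for span in tl.spans:
        f0, f1 = span.frames(tl.fps)
        expected = State.ACTIVE if span.state == "active" else State.HOVER
        assert (states[span.channel][f0:f1] == expected).all()


def test_scan_rejects_resolution_mismatch(toy_xi, rng):
    frames = rng.integers(0, 256, size=(3, 240, 848, 3), dtype=np.uint8)
    with pytest.raises(GeometryError):
        scan_video(frames, toy_xi)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

I, H, A = "inactive", "hover", "active"


@pytest.mark.parametrize("states,kwargs,expected", [
    ([I, A, A, I, A], {}, [(1, 3), (4, 5)]),
    ([I] * 5, {}, []),
    ([A, A, A], {}, [(0, 3)]),
    ([A, I, A], {"min_gap_frames": 2}, [(0, 3)]),
    ([A, H, A], {}, [(0, 1), (2, 3)]),           # hover breaks a run
    ([H, H, H], {}, []),                          # hover alone is no event
    ([A, I, I, A], {"min_gap_frames": 2}, [(0, 1), (3, 4)]),
    ([A, A, I, A, A, A], {"min_gap_frames": 2, "min_duration_frames": 6},
     [(0, 6)]),
])
def test_events_from_states_examples(states, kwargs, expected):
    records = events_from_states(states, fps=15.0, **kwargs)
    assert [(r.start_frame, r.end_frame) for r in records] == expected
    for r in records:
        assert r.start_s == r.start_frame / 15.0
        assert r.duration_s == (r.end_frame - r.start_frame) / 15.0


def test_events_from_states_rejects_bad_parameters():
    with pytest.raises(ParameterError):
        events_from_states([A], fps=0.0)
    with pytest.raises(ParameterError):
        events_from_states([], fps=15.0)
    with pytest.raises(ParameterError):
        events_from_states([A], fps=15.0, min_gap_frames=0)


def test_exhaustive_agreement_with_bruteforce_runs():
    """Default debounce equals the maximal-run oracle on every binary
    sequence up to length 12."""
    for n in range(1, 13):
        for bits in range(2 ** n):
            states = [(bits >> k) & 1 and A or I for k in range(n)]
            got = [(r.start_frame, r.end_frame)
                   for r in events_from_states(states, fps=15.0)]
            assert got == maximal_active_runs(states)


@given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=60),
       st.integers(1, 4), st.integers(1, 4))
def test_debounce_agrees_with_bruteforce(states, min_dur, min_gap):
    got = [(r.start_frame, r.end_frame)
           for r in events_from_states(states, fps=15.0,
                                       min_duration_frames=min_dur,
                                       min_gap_frames=min_gap)]
    assert got == debounced_runs(states, min_dur, min_gap)


@given(st.lists(st.sampled_from([0, 2]), min_size=1, max_size=40),
       st.integers(1, 5), st.integers(1, 5))
def test_debounce_monotonicity(states, min_dur, min_gap):
    """Raising either debounce parameter never increases the event count."""
    base = len(events_from_states(states, 15.0, min_duration_frames=min_dur,
                                  min_gap_frames=min_gap))
    more_dur = len(events_from_states(states, 15.0,
                                      min_duration_frames=min_dur + 1,
                                      min_gap_frames=min_gap))
    more_gap = len(events_from_states(states, 15.0,
                                      min_duration_frames=min_dur,
                                      min_gap_frames=min_gap + 1))
    assert more_dur <= base
    assert more_gap <= base


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_detect_events_counts_match_script(toy_xi):
    tl = random_timeline(toy_xi, duration_s=12, seed=21)
    frames, truth = generate_console_video(tl, toy_xi, SyntheticScene(seed=5))
    log = detect_events(frames, toy_xi)
    assert log.counts_dict() == truth.counts_dict()
    assert log.counts_dict() == {
        ch.value: n for ch, n in tl.scripted_counts().items()
    }


def test_detect_events_empty_timeline_zero_counts(toy_xi):
    from surgevents import EventTimeline

    tl = EventTimeline(spans=[], fps=15.0, duration_s=2.0, resolution=(320, 180))
    frames, truth = generate_console_video(tl, toy_xi, SyntheticScene(seed=6))
    log = detect_events(frames, toy_xi)
    assert log.counts == {} and truth.counts == {}


def test_detect_events_is_deterministic_byte_identical(toy_xi, tmp_path):
    tl = random_timeline(toy_xi, duration_s=8, seed=31)
    frames, _ = generate_console_video(tl, toy_xi, SyntheticScene(seed=7))
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    detect_events(frames, toy_xi, video_id="v").to_csv(a)
    detect_events(frames, toy_xi, video_id="v").to_csv(b)
    assert a.read_bytes() == b.read_bytes()
    assert len(a.read_bytes()) > 0


def test_event_log_counts_consistent_with_events(toy_xi):
    tl = random_timeline(toy_xi, duration_s=10, seed=41)
    frames, _ = generate_console_video(tl, toy_xi, SyntheticScene(seed=8))
    log = detect_events(frames, toy_xi)
    for channel, n in log.counts.items():
        assert n == sum(1 for e in log.events if e.channel == channel)
    starts = [e.start_frame for e in log.events]
    assert starts == sorted(starts)
    assert all(e.end_frame <= log.n_frames for e in log.events)
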