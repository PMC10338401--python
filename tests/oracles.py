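"""Independent brute-force reference implementations used only by tests.

Each oracle is written as plainly as possible, without reusing package
internals, so that agreement between the package and an oracle is evidence
rather than tautology.
"""

import math


def maximal_active_runs(states):
    """All maximal runs of 'active' frames as half-open (start, end) pairs.

    ``states`` is a sequence of strings 'inactive'/'hover'/'active' or the
    corresponding int codes 0/1/2.
    """
    def is_active(s):
        return s == "active" or s == 2

    runs = []
    start = None
    for i, s in enumerate(states):
        if is_active(s) and start is None:
            start = i
        elif not is_active(s) and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(states)))
    return runs


def debounced_runs(states, min_duration=1, min_gap=1):
    """Maximal active runs after gap-merging then short-run dropping."""
    runs = maximal_active_runs(states)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_duration]


def polyline_length(points):
    """Sum of Euclidean segment lengths along a point sequence."""
    total = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total


def pair_start_stop(events):
    """Brute-force START/STOP pairing: a STOP closes the latest still-open
    START of the same behavior. ``events`` is (time, behavior, status).

    Returns (behavior, start, stop) triples; raises ValueError on
    unmatched events.
    """
    open_starts = []  # list of [time, behavior, open?]
    intervals = []
    for time, behavior, status in events:
        if status == "START":
            open_starts.append([time, behavior])
        else:
            for k in range(len(open_starts) - 1, -1, -1):
                if open_starts[k][1] == behavior:
                    start, _ = open_starts.pop(k)
                    intervals.append((behavior, start, time))
                    break
            else:
                raise ValueError(f"unmatched STOP for {behavior}")
    if open_starts:
        raise ValueError(f"unclosed STARTs: {open_starts}")
    return sorted(intervals, key=lambda t: (t[1], t[2], t[0]))


def two_pass_mean_sd(values):
    """Textbook two-pass mean and sample standard deviation."""
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, float("nan")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)
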