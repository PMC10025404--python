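"""Small utilities for lists of (start_s, end_s) time intervals.

Intervals are half-open ``[start, end)`` in seconds and kept sorted and
non-overlapping by the functions here.
"""

from __future__ import annotations

import numpy as np

Interval = tuple[float, float]


def normalize(intervals: list[Interval]) -> list[Interval]:
    """Sort intervals, drop empty ones, and merge overlaps/adjacencies."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    merged: list[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def total_duration(intervals: list[Interval]) -> float:
    return float(sum(b - a for a, b in intervals))


def max_duration(intervals: list[Interval]) -> float:
    return float(max((b - a for a, b in intervals), default=0.0))


def clip_to_window(intervals: list[Interval], window: Interval) -> list[Interval]:
    """Restrict intervals to ``window``, clipping partial overlaps."""
    w0, w1 = window
    out = []
    for a, b in intervals:
        a2, b2 = max(a, w0), min(b, w1)
        if b2 > a2:
            out.append((a2, b2))
    return out


def mask_from_intervals(times: np.ndarray, intervals: list[Interval]) -> np.ndarray:
    """Boolean mask over ``times`` marking samples inside any interval."""
    mask = np.zeros(times.shape, dtype=bool)
    for a, b in intervals:
        mask |= (times >= a) & (times < b)
    return mask


def intervals_from_mask(mask: np.ndarray, times: np.ndarray) -> list[Interval]:
    """Maximal runs of True in ``mask`` as [start, end) intervals.

    The end of a run is the time of the first sample after it (or the last
    time plus one step), so a run of k samples at step dt has duration k*dt.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    out = []
    for s, e in zip(starts, ends):
        t_end = times[e] if e < times.size else times[-1] + dt
        out.append((float(times[s]), float(t_end)))
    return out


def complement(intervals: list[Interval], span: Interval) -> list[Interval]:
    """Gaps of ``span`` not covered by ``intervals``."""
    ivs = normalize(clip_to_window(intervals, span))
    out: list[Interval] = []
    cursor = span[0]
    for a, b in ivs:
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if span[1] > cursor:
        out.append((cursor, span[1]))
    return out
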