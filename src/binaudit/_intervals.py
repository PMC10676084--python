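"""Interval algebra on 0-based half-open (start, end) pairs.

All public functions accept any iterable of (start, end) tuples and return
sorted, maximal, disjoint interval lists. Depth (pileup) computation uses a
difference-array so stacks of overlapping intervals cost O(n + L).
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

import numpy as np

Pair = Tuple[int, int]


def merge(intervals: Iterable[Pair]) -> List[Pair]:
    """Union of intervals as sorted maximal disjoint intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Pair] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect(a: Iterable[Pair], b: Iterable[Pair]) -> List[Pair]:
    """Intersection of two interval sets (inputs need not be merged)."""
    am, bm = merge(a), merge(b)
    out: List[Pair] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if e > s:
            out.append((s, e))
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def union(a: Iterable[Pair], b: Iterable[Pair]) -> List[Pair]:
    return merge(list(a) + list(b))


def total_length(intervals: Iterable[Pair]) -> int:
    return sum(e - s for s, e in merge(intervals))


def clip(intervals: Iterable[Pair], start: int, end: int) -> List[Pair]:
    """Restrict an interval set to the window [start, end)."""
    return intersect(intervals, [(start, end)])


def coverage(intervals: Iterable[Pair], length: int) -> np.ndarray:
    """Per-base depth over [0, length); intervals are clipped to the window."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for s, e in intervals:
        s = max(0, int(s))
        e = min(length, int(e))
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:length])
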