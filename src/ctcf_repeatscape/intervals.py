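"""Small interval utilities on 0-based half-open coordinates.

These back several modules (overlap classification, gap complements); they are
deliberately numpy-based so event sets of a few thousand intervals stay cheap.
"""

from __future__ import annotations

import numpy as np


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting intervals; returns sorted disjoint set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    s_starts: np.ndarray,
    s_ends: np.ndarray,
) -> np.ndarray:
    """Boolean array: does each query interval overlap (>=1 bp) any subject?"""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    ms, me = merge(np.asarray(s_starts), np.asarray(s_ends))
    if ms.size == 0:
        return np.zeros(q_starts.shape, dtype=bool)
    # first merged interval whose end is > q_start; it overlaps iff its start < q_end
    idx = np.searchsorted(me, q_starts, side="right")
    hit = idx < ms.size
    out = np.zeros(q_starts.shape, dtype=bool)
    out[hit] = ms[idx[hit]] < q_ends[hit]
    return out


def contained_in_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    s_starts: np.ndarray,
    s_ends: np.ndarray,
) -> np.ndarray:
    """Boolean array: is each query fully inside some merged subject interval?"""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    ms, me = merge(np.asarray(s_starts), np.asarray(s_ends))
    if ms.size == 0:
        return np.zeros(q_starts.shape, dtype=bool)
    idx = np.searchsorted(ms, q_starts, side="right") - 1
    ok = idx >= 0
    out = np.zeros(q_starts.shape, dtype=bool)
    out[ok] = q_ends[ok] <= me[idx[ok]]
    return out


def point_in_any(points: np.ndarray, s_starts: np.ndarray, s_ends: np.ndarray) -> np.ndarray:
    """Boolean array: does each point fall inside [start, end) of any subject?"""
    points = np.asarray(points, dtype=np.int64)
    return overlaps_any(points, points + 1, s_starts, s_ends)


def complement(starts: np.ndarray, ends: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaps of [0, length) not covered by the (merged) intervals."""
    ms, me = merge(starts, ends)
    ms = np.clip(ms, 0, length)
    me = np.clip(me, 0, length)
    gs = np.concatenate([[0], me])
    ge = np.concatenate([ms, [length]])
    keep = ge > gs
    return gs[keep], ge[keep]


def total_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total merged base coverage."""
    ms, me = merge(starts, ends)
    return int(np.sum(me - ms))
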