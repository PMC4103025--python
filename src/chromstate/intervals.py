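"""Sorted half-open interval arithmetic on numpy arrays.

An interval set on one chromosome is a pair of equal-length int64 arrays
``(starts, ends)`` that is sorted, non-overlapping and non-adjacent after
:func:`merge`. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np

IntervalArray = tuple[np.ndarray, np.ndarray]

_EMPTY = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))


def empty() -> IntervalArray:
    return _EMPTY


def as_intervals(starts, ends) -> IntervalArray:
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have the same length")
    if np.any(e <= s):
        raise ValueError("all intervals must satisfy start < end")
    return s, e


def merge(starts, ends, gap: int = 0) -> IntervalArray:
    """Union of intervals; intervals closer than ``gap`` are joined.

    ``gap=0`` joins touching intervals ([0,5)+[5,9) -> [0,9)).
    """
    s, e = as_intervals(starts, ends)
    if s.size == 0:
        return _EMPTY
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1] + gap:
            if b > out_e[-1]:
                out_e[-1] = b
        else:
            out_s.append(a)
            out_e.append(b)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def clip(ivals: IntervalArray, lo: int, hi: int) -> IntervalArray:
    s, e = ivals
    s = np.clip(s, lo, hi)
    e = np.clip(e, lo, hi)
    keep = e > s
    return s[keep], e[keep]


def complement(ivals: IntervalArray, length: int) -> IntervalArray:
    """Gaps of a merged interval set within [0, length)."""
    s, e = ivals
    bounds_s = np.concatenate(([0], e))
    bounds_e = np.concatenate((s, [length]))
    keep = bounds_e > bounds_s
    return bounds_s[keep].astype(np.int64), bounds_e[keep].astype(np.int64)


def subtract(a: IntervalArray, b: IntervalArray, length: int) -> IntervalArray:
    """Set difference a \\ b; both must be merged; result within [0, length)."""
    return intersect(a, complement(b, length))


def intersect(a: IntervalArray, b: IntervalArray) -> IntervalArray:
    sa, ea = a
    sb, eb = b
    out_s, out_e = [], []
    i = j = 0
    while i < sa.size and j < sb.size:
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if hi > lo:
            out_s.append(lo)
            out_e.append(hi)
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_length(ivals: IntervalArray) -> int:
    s, e = ivals
    return int(np.sum(e - s))


def overlap_lengths(ivals: IntervalArray, qs, qe) -> np.ndarray:
    """Total overlap (bp) of each query [qs, qe) with a merged interval set.

    Vectorised over queries via prefix sums of interval lengths.
    """
    s, e = ivals
    qs = np.asarray(qs, dtype=np.int64)
    qe = np.asarray(qe, dtype=np.int64)
    if s.size == 0:
        return np.zeros(qs.shape, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(e - s)))

    def mass_below(x):
        # total covered bp in [0, x)
        i = np.searchsorted(s, x, side="right")  # intervals starting before x
        inside = np.clip(x - s[np.maximum(i - 1, 0)], 0, (e - s)[np.maximum(i - 1, 0)])
        inside = np.where(i > 0, inside, 0)
        return cum[np.maximum(i - 1, 0)] + inside

    return mass_below(qe) - mass_below(qs)


def any_overlap(ivals: IntervalArray, qs, qe) -> np.ndarray:
    """Boolean: does each query [qs, qe) overlap the merged set at all?"""
    s, e = ivals
    qs = np.asarray(qs, dtype=np.int64)
    qe = np.asarray(qe, dtype=np.int64)
    if s.size == 0:
        return np.zeros(qs.shape, dtype=bool)
    # candidate: last interval with start < qe
    i = np.searchsorted(s, qe, side="left") - 1
    cand = i >= 0
    hit = np.zeros(qs.shape, dtype=bool)
    hit[cand] = e[i[cand]] > qs[cand]
    return hit
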