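"""Half-open interval arithmetic on (n, 2) int64 numpy arrays.

All coordinates are 0-based half-open. "Merged" means sorted by start with
overlapping or touching intervals coalesced; most consumers here merge first
and then use the two-pointer primitives below.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

GenomicIntervals = Mapping[str, np.ndarray]  # chrom -> merged (n, 2) array

_EMPTY = np.empty((0, 2), dtype=np.int64)


def as_array(intervals: Iterable[tuple[int, int]] | np.ndarray) -> np.ndarray:
    arr = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals)
    if arr.size == 0:
        return _EMPTY.copy()
    arr = arr.reshape(-1, 2).astype(np.int64)
    if np.any(arr[:, 0] > arr[:, 1]):
        raise ValueError("interval start > end")
    return arr


def merge(intervals: Iterable[tuple[int, int]] | np.ndarray) -> np.ndarray:
    """Union of intervals: sorted, overlapping/touching runs coalesced."""
    arr = as_array(intervals)
    arr = arr[arr[:, 1] > arr[:, 0]]  # drop empty
    if len(arr) == 0:
        return _EMPTY.copy()
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(intervals: np.ndarray) -> int:
    arr = as_array(intervals)
    if len(arr) == 0:
        return 0
    return int(np.sum(arr[:, 1] - arr[:, 0]))


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged sets, as a merged set (two-pointer sweep)."""
    a, b = as_array(a), as_array(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def overlap_length(a: np.ndarray, b: np.ndarray) -> int:
    return total_length(intersect(merge(a), merge(b)))


def interval_overlap(start: int, end: int, merged: np.ndarray) -> int:
    """Total bp of [start, end) covered by a merged set."""
    merged = as_array(merged)
    if len(merged) == 0 or end <= start:
        return 0
    lo = np.maximum(merged[:, 0], start)
    hi = np.minimum(merged[:, 1], end)
    return int(np.sum(np.maximum(hi - lo, 0)))


def clip_interval(start: int, end: int, merged: np.ndarray) -> list[tuple[int, int]]:
    """Pieces of [start, end) inside a merged set, in order."""
    merged = as_array(merged)
    out = []
    for s, e in merged:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((int(lo), int(hi)))
    return out


def pad(intervals: np.ndarray, amount: int, chrom_length: int | None = None) -> np.ndarray:
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr.copy()
    arr[:, 0] = np.maximum(arr[:, 0] - amount, 0)
    arr[:, 1] = arr[:, 1] + amount
    if chrom_length is not None:
        arr[:, 1] = np.minimum(arr[:, 1], chrom_length)
    return merge(arr)


def coverage_function(merged: np.ndarray):
    """F with F(x) = bp of [0, x) covered by a merged set; accepts arrays."""
    merged = as_array(merged)
    starts, ends = merged[:, 0], merged[:, 1]
    lens = ends - starts
    cum = np.concatenate([[0], np.cumsum(lens)])

    def F(x):
        x = np.asarray(x, dtype=np.int64)
        idx = np.searchsorted(starts, x, side="right") - 1
        safe = np.maximum(idx, 0)
        partial = np.clip(x - starts[safe], 0, lens[safe])
        return np.where(idx >= 0, cum[safe] + partial, 0)

    return F


def batch_overlap(starts, ends, merged: np.ndarray) -> np.ndarray:
    """Vectorized overlap of query intervals with a merged set."""
    merged = as_array(merged)
    if len(merged) == 0:
        return np.zeros(len(np.atleast_1d(starts)), dtype=np.int64)
    F = coverage_function(merged)
    return F(ends) - F(starts)


def merge_by_chrom(records: Iterable[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Group (chrom, start, end) records and merge per chromosome."""
    grouped: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in records:
        grouped.setdefault(chrom, []).append((start, end))
    return {chrom: merge(ivs) for chrom, ivs in grouped.items()}
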