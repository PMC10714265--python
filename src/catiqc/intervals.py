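"""Half-open interval arithmetic used for monitoring sessions and activity time.

Intervals are ``(start, end)`` pairs of comparable values (datetimes or
numbers) with ``start <= end``; all operations treat them as half-open
``[start, end)`` so abutting intervals merge without double counting.
"""
from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence, TypeVar

T = TypeVar("T")


def merge(intervals: Iterable[tuple[T, T]]) -> list[tuple[T, T]]:
    """Union of intervals: sorted, pairwise-disjoint, non-abutting."""
    items = sorted((a, b) for a, b in intervals if not b < a)
    out: list[tuple[T, T]] = []
    for a, b in items:
        if out and a <= out[-1][1]:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def total_seconds(intervals: Iterable[tuple[dt.datetime, dt.datetime]]) -> float:
    """Total length in seconds of the union of datetime intervals."""
    return sum((b - a).total_seconds() for a, b in merge(intervals))


def clip(
    intervals: Iterable[tuple[T, T]], lo: T, hi: T
) -> list[tuple[T, T]]:
    """Restrict intervals to [lo, hi); empty pieces are dropped."""
    out = []
    for a, b in intervals:
        a2, b2 = max(a, lo), min(b, hi)
        if a2 < b2:
            out.append((a2, b2))
    return out


def gaps(intervals: Sequence[tuple[T, T]]) -> list[tuple[T, T]]:
    """Complement gaps between the merged intervals (within their span)."""
    merged = merge(intervals)
    return [
        (merged[i][1], merged[i + 1][0])
        for i in range(len(merged) - 1)
        if merged[i][1] < merged[i + 1][0]
    ]
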