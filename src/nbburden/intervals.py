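"""Half-open genomic interval arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)``
(BED convention).  These helpers implement the exact overlap, merge and
containment semantics the burden pipeline relies on: a single shared base
counts as overlap; abutting intervals (``a.end == b.start``) do not
overlap but do merge into one block.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def as_interval_frame(intervals: pd.DataFrame | Iterable[Sequence]) -> pd.DataFrame:
    """Coerce an iterable of (chrom, start, end[, ...]) into a DataFrame.

    Raises ``ValueError`` on negative coordinates or ``end <= start``
    (zero-length intervals carry no bases and are rejected).
    """
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
        missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"interval frame lacks columns {missing}")
    else:
        rows = list(intervals)
        if rows and len(rows[0]) > 3:
            df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS + ["name"][: len(rows[0]) - 3])
        else:
            df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if len(df) and ((df["start"] < 0).any() or (df["end"] <= df["start"]).any()):
        raise ValueError("intervals must satisfy 0 <= start < end")
    return df


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals on one chromosome.

    Abutting intervals are fused, so the output blocks are maximal,
    disjoint and sorted.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if end <= start:
            raise ValueError("intervals must satisfy start < end")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Number of distinct bases covered by a set of intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True when the two half-open intervals share at least one base."""
    return a_start < b_end and b_start < a_end


def any_overlap(
    starts: np.ndarray, ends: np.ndarray, other: list[tuple[int, int]]
) -> np.ndarray:
    """Vectorised: for each query interval, does it overlap any merged block?

    ``other`` must be sorted and non-overlapping (output of
    :func:`merge_intervals`).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if not other:
        return np.zeros(len(starts), dtype=bool)
    o_starts = np.array([s for s, _ in other], dtype=np.int64)
    o_ends = np.array([e for _, e in other], dtype=np.int64)
    # candidate block: last block whose start < query end
    idx = np.searchsorted(o_starts, ends, side="left") - 1
    hit = np.zeros(len(starts), dtype=bool)
    ok = idx >= 0
    hit[ok] = o_ends[idx[ok]] > starts[ok]
    return hit


def intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total number of bases shared between two interval sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = shared = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            shared += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return shared
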