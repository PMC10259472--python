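"""Genomic interval utilities.

All coordinates are 0-based, half-open ``[start, end)``. BLAST-style
1-based inclusive coordinates are converted at the readers, never here.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(
    intervals: Iterable[tuple[int, int]], *, merge_abutting: bool = False
) -> list[tuple[int, int]]:
    """Union of half-open intervals.

    Overlapping intervals are merged; abutting intervals (``a.end ==
    b.start``) are merged only when *merge_abutting* is set, because a
    zero-length overlap is not an overlap.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"degenerate interval [{s}, {e})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged:
            ps, pe = merged[-1]
            if s < pe or (merge_abutting and s == pe):
                merged[-1] = (ps, max(pe, e))
                continue
        merged.append((s, e))
    return merged


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of positions covered by the union of intervals."""
    ivs = list(intervals)
    if not ivs:
        return 0
    return sum(e - s for s, e in merge_intervals(ivs))


def overlap_components(intervals: Sequence[tuple[int, int]]) -> list[list[int]]:
    """Group interval indices into connected components of pairwise overlap.

    Two intervals are connected when they strictly overlap; the transitive
    closure defines the components (chains of overlaps collapse into one
    group). Returns lists of indices into *intervals*, each sorted, and the
    list of groups ordered by leftmost start.
    """
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    groups: list[list[int]] = []
    current: list[int] = []
    reach = None
    for i in order:
        s, e = intervals[i]
        if s >= e:
            raise ValueError(f"degenerate interval [{s}, {e})")
        if current and s < reach:
            current.append(i)
            reach = max(reach, e)
        else:
            if current:
                groups.append(sorted(current))
            current = [i]
            reach = e
    if current:
        groups.append(sorted(current))
    return groups
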