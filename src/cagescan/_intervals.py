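"""Half-open genomic interval arithmetic shared across modules.

All coordinates are 0-based, half-open ``[start, end)``. Blocks (the BED12
sub-structure) are lists of such intervals; the canonical form is sorted,
non-overlapping and non-adjacent (touching blocks are merged, as a read pair
covering ``[100,136)`` and ``[136,160)`` spans one contiguous region).
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_blocks(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, merging overlaps and adjacency.

    Returns the canonical sorted block list. Raises ``ValueError`` on an
    empty or inverted interval.
    """
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"invalid interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def blocks_are_canonical(blocks: Sequence[Interval]) -> bool:
    """True iff blocks are sorted, non-empty, and separated by gaps >= 1."""
    if not blocks:
        return False
    prev_end = None
    for s, e in blocks:
        if s >= e:
            return False
        if prev_end is not None and s <= prev_end:
            return False
        prev_end = e
    return True
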