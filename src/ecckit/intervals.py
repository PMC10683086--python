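"""Genome interval arithmetic on sorted NumPy arrays.

All coordinates are 0-based half-open. The merged representation used
throughout the package is ``{chrom: (starts, ends)}`` with disjoint,
sorted interval arrays per chromosome.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

Merged = dict[str, tuple[np.ndarray, np.ndarray]]


def merge(intervals: Iterable[tuple[str, int, int]]) -> Merged:
    """Merge possibly overlapping (chrom, start, end) triples.

    Touching intervals are coalesced; the set of covered bases is the
    same either way, and downstream queries only depend on coverage.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    out: Merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return out


def covered_bases(merged: Merged) -> int:
    """Total number of bases covered by a merged interval set."""
    return int(sum((e - s).sum() for s, e in merged.values()))


def points_in(merged: Merged, chrom: str, positions) -> np.ndarray:
    """Boolean mask over ``positions`` lying inside the merged set."""
    pos = np.asarray(positions, dtype=np.int64)
    res = np.zeros(pos.shape, dtype=bool)
    if chrom not in merged:
        return res
    starts, ends = merged[chrom]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res[ok] = pos[ok] < ends[idx[ok]]
    return res


def point_in(merged: Merged, chrom: str, pos: int) -> bool:
    """True if a single position lies inside the merged set."""
    return bool(points_in(merged, chrom, [pos])[0])


def overlaps(merged: Merged, chrom: str, start: int, end: int) -> bool:
    """True if [start, end) overlaps the merged set by >= 1 bp."""
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    # number of merged intervals starting strictly before `end`
    idx = int(np.searchsorted(starts, end, side="left"))
    return idx > 0 and int(ends[idx - 1]) > start
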