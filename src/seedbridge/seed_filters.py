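"""Seed filters: SMEM extraction and maximal-spanning-seed extraction.

Both filters operate on a duplicate-free set of MEMs and select subsets
defined purely by query-interval geometry:

* a *SMEM* (super-maximal exact match) is a MEM whose query interval is not
  enclosed by the query interval of any other MEM;
* a *maximal spanning seed* is a MEM with at least one query position at
  which no strictly longer MEM covers that position.

Every maximal spanning seed is a SMEM, so
``filter_max_spanning(M) <= filter_smems(M) <= M`` for every MEM set M,
and the maximal-spanning filter may equivalently be fed SMEMs.

Both run in O(n log n): the SMEM filter as a single sweep over the MEMs
sorted by query start, the maximal-spanning filter with an interval tree
over query intervals and a length heap at the sweep position.
"""

from __future__ import annotations

import heapq
from bisect import bisect_right
from typing import Iterable

from intervaltree import IntervalTree

from .seed_model import Seed


def _check_duplicate_free(seeds: Iterable[Seed]) -> list[Seed]:
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("MEM input must be a duplicate-free set of (q, r, l) triples")
    return seeds


def filter_smems(mems: list[Seed]) -> list[Seed]:
    """Extract the SMEMs: MEMs not enclosed by another MEM on the query.

    Sweep over the MEMs sorted by (query start ascending, length
    descending), so any seed enclosing another is visited first.  ``qend``
    tracks the rightmost query end seen so far: a seed ending at or before
    ``qend`` is enclosed by an earlier seed — unless it spans exactly the
    same query interval as the last emitted SMEM (same q, same end, hence a
    different reference interval), in which case it is a SMEM too and is
    emitted as well.
    """
    mems = _check_duplicate_free(mems)
    ordered = sorted(mems, key=lambda s: (s.q, -s.l))
    out: list[Seed] = []
    qend = -1  # rightmost query end visited
    qstart = -1  # query start of the last emitted SMEM
    for s in ordered:
        if s.q_end > qend:
            out.append(s)
            qend = s.q_end
            qstart = s.q
        elif s.q == qstart and s.q_end == qend:
            out.append(s)
    return out


def tie_spanning_at(qpos: int, T: list[Seed]) -> list[Seed]:
    """All seeds of maximal length among the seeds ``T`` overlapping
    ``qpos``; ties by length are all returned.  Empty ``T`` yields []."""
    if not T:
        return []
    heap = [(-s.l, s.q, s.r, s) for s in T]
    heapq.heapify(heap)
    top_len = -heap[0][0]
    out: list[Seed] = []
    while heap and -heap[0][0] == top_len:
        out.append(heapq.heappop(heap)[3])
    return out


def filter_max_spanning(mems: list[Seed]) -> list[Seed]:
    """Extract the maximal spanning seeds: MEMs with at least one query
    position not covered by any strictly longer MEM.

    An interval tree over query intervals drives a sweep position ``qpos``.
    At each ``qpos`` the seeds overlapping it are heapified by length and
    all seeds of maximal length are emitted (a seed covered everywhere only
    by equal-length seeds is still maximal spanning: "longer" is strict).
    ``qpos`` then jumps to the nearest position where the set of covering
    maximal seeds can change — the smallest query end among the seeds just
    emitted, or the next seed start, whichever comes first.  Across
    seed-free stretches ``qpos`` jumps directly to the next seed start.
    Each iteration either emits or crosses a seed start, so the loop runs
    at most 2n times.
    """
    mems = _check_duplicate_free(mems)
    if not mems:
        return []
    tree = IntervalTree()
    for s in mems:
        tree.addi(s.q, s.q_end, s)
    starts = sorted({s.q for s in mems})
    emitted: dict[tuple[int, int, int], Seed] = {}

    qpos = starts[0]
    max_end = max(s.q_end for s in mems)
    while qpos < max_end:
        overlapping = [iv.data for iv in tree[qpos]]
        if overlapping:
            top = tie_spanning_at(qpos, overlapping)
            for s in top:
                emitted[(s.q, s.r, s.l)] = s
            next_change = min(s.q_end for s in top)
        else:
            next_change = max_end
        j = bisect_right(starts, qpos)
        if j < len(starts):
            next_change = min(next_change, starts[j])
        if next_change <= qpos:  # defensive; ends/starts are always > qpos
            next_change = qpos + 1
        qpos = next_change

    order = {(s.q, s.r, s.l): i for i, s in enumerate(sorted(mems, key=lambda s: (s.q, -s.l, s.r)))}
    return sorted(emitted.values(), key=lambda s: order[(s.q, s.r, s.l)])
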