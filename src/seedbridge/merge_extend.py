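"""Merge-extend construction of maximal exact matches (MEMs) from
fixed-size seeds.

The idea: seeds drawn as 45-degree lines in the reference x query plane lie
on diagonals indexed by their delta value ``r - q``.  Sorting the fixed-size
seeds by ``(delta, q)`` places attached seeds (same diagonal, overlapping or
touching reference intervals) consecutively, so one linear pass merges each
chain of attached seeds into a single long seed.  Two complications arise
when the reference index is sampled (m-step k-mers or (w, k)-minimizers)
rather than dense:

1. adjacent sampled k-mers on a diagonal can be separated by a gap of up to
   ``m - k`` matching characters; the merge pass closes such gaps by
   character-verified extension and merges on success;
2. the ends of a MEM need not be covered by sampled k-mers, so every merged
   seed is finally extended maximally in both directions.

With maximal sampling distance ``m`` (the step size, or the minimizer
window ``w``), the construction produces every MEM of length at least
``m + k - 1`` exactly once, and never walks a seed end more than ``m - 1``
characters before meeting its neighbour or hitting a mismatch.  This is the
merge-extend strategy; contrast with the extend-purge strategy
(:func:`seedbridge.oracle.extend_purge_baseline`) which extends every seed
independently and must deduplicate afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .seed_model import Seed, Sequence, chars_match, seed_is_exact_match


@dataclass
class MergeParams:
    """Parameters of the merge-extend pass.

    ``m`` is the maximal sampling distance of the index that produced the
    input seeds: the step size for m-step k-mer indexes, the window size for
    (w, k)-minimizer indexes, 1 for a full index.  ``min_out_len`` defaults
    to ``m + k - 1``, the completeness threshold: every MEM at least that
    long is guaranteed to be produced.  It may be lowered (down to ``k``) to
    also emit shorter MEMs, which are then complete only insofar as the
    sampled index happened to contain their k-mers.
    """

    k: int
    m: int = 1
    min_out_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1:
            raise ValueError(f"k and m must be >= 1, got k={self.k}, m={self.m}")
        if self.min_out_len is None:
            self.min_out_len = self.m + self.k - 1
        if self.min_out_len < 1:
            raise ValueError(f"min_out_len must be >= 1, got {self.min_out_len}")


@dataclass
class MergeStats:
    """Operation counters for comparing against the extend-purge strategy."""

    chars_compared: int = 0
    extension_steps: int = 0  # successful 1-nt advances, both phases
    phase1_extension_steps: int = 0
    max_phase1_advance: int = 0  # longest single gap-closing walk
    seeds_merged: int = 0
    duplicates_purged: int = 0  # always 0: merge-extend creates none

    @property
    def total_work(self) -> int:
        return self.extension_steps + self.duplicates_purged


def sort_for_merge(seeds: list[Seed]) -> list[Seed]:
    """Stable sort by (delta, q) ascending, making attached seeds
    consecutive.  Seeds with equal delta and equal q cannot coexist, since
    distinct (q, r) pairs differ in delta or in q."""
    return sorted(seeds, key=lambda s: (s.delta, s.q))


def _is_sorted_for_merge(seeds: list[Seed]) -> bool:
    return all(
        (a.delta, a.q) <= (b.delta, b.q) for a, b in zip(seeds, seeds[1:])
    )


def merge_only(seeds: list[Seed]) -> list[Seed]:
    """Linear-time merge of attached consecutive seeds, for input already
    sorted by (delta, q).

    This is the fast path for seed producers that deliver seeds
    delta-sorted: no sorting and no character comparisons are needed.  It
    performs no gap closing, so it computes complete MEM sets only for
    step-1 (dense) input, where gaps cannot occur.
    """
    if not _is_sorted_for_merge(seeds):
        raise ValueError("merge_only requires input sorted by (delta, q)")
    if not seeds:
        return []
    out: list[Seed] = []
    cur_q, cur_r, cur_end = seeds[0].q, seeds[0].r, seeds[0].r_end
    cur_delta = seeds[0].delta
    for s in seeds[1:]:
        if s.delta == cur_delta and s.r <= cur_end:
            cur_end = max(cur_end, s.r_end)
        else:
            out.append(Seed(cur_q, cur_r, cur_end - cur_r))
            cur_q, cur_r, cur_end = s.q, s.r, s.r_end
            cur_delta = s.delta
    out.append(Seed(cur_q, cur_r, cur_end - cur_r))
    return out


def merge_and_extend(
    Q: Sequence,
    R: Sequence,
    seeds: list[Seed],
    params: MergeParams,
    validate: bool = False,
    stats: Optional[MergeStats] = None,
) -> list[Seed]:
    """Compute MEMs from fixed-size seeds by merge, gap closing and final
    maximal extension.

    Phase 1 walks the (delta, q)-sorted seeds once.  Within a diagonal, the
    current merged seed is grown: an attached successor is absorbed
    directly; a successor behind a gap is reached by comparing query and
    reference characters across the gap, merging if every gap character
    matches.  On the first mismatch inside a gap the current seed is
    finalized, keeping the partial rightward extension — those characters
    belong to the current MEM's true end and cannot be extended past the
    mismatch later either.

    Phase 2 extends every finalized seed maximally leftwards and rightwards,
    stopping at the first mismatch or sequence boundary.

    The output contains every MEM of length >= ``params.min_out_len``
    reachable from the input seeds, each exactly once, sorted by
    (delta, q).  With ``validate=True`` each input seed is first re-checked
    to be an exact match over (Q, R); intended for tests, off by default.
    """
    if stats is None:
        stats = MergeStats()
    if validate:
        for s in seeds:
            if not seed_is_exact_match(s, Q, R):
                raise ValueError(f"input seed {s} is not an exact match over (Q, R)")

    ordered = sort_for_merge(seeds)
    merged: list[Seed] = []
    qc, rc = Q.chars, R.chars
    len_q, len_r = len(qc), len(rc)

    i = 0
    n = len(ordered)
    while i < n:
        cur = ordered[i]
        cur_q, cur_r, cur_end = cur.q, cur.r, cur.r_end
        cur_delta = cur.delta
        i += 1
        while i < n and ordered[i].delta == cur_delta:
            nxt = ordered[i]
            if nxt.r <= cur_end:
                # attached: absorb
                cur_end = max(cur_end, nxt.r_end)
                stats.seeds_merged += 1
                i += 1
                continue
            # gap on the diagonal: try to close it by character comparison
            gap = nxt.r - cur_end
            advance = 0
            qpos = cur_end - cur_delta
            while advance < gap:
                stats.chars_compared += 1
                if not chars_match(qc[qpos + advance], rc[cur_end + advance]):
                    break
                advance += 1
            stats.phase1_extension_steps += advance
            stats.extension_steps += advance
            stats.max_phase1_advance = max(stats.max_phase1_advance, advance)
            if advance == gap:
                cur_end = nxt.r_end
                stats.seeds_merged += 1
                i += 1
                continue
            # mismatch inside the gap: finalize, keeping the partial extension
            cur_end += advance
            merged.append(Seed(cur_q, cur_r, cur_end - cur_r))
            cur = nxt
            cur_q, cur_r, cur_end = cur.q, cur.r, cur.r_end
            i += 1
        merged.append(Seed(cur_q, cur_r, cur_end - cur_r))

    # Phase 2: maximal extension of every merged seed in both directions.
    out: list[Seed] = []
    min_len = int(params.min_out_len)  # type: ignore[arg-type]
    for s in merged:
        q, r, end = s.q, s.r, s.r_end
        while q > 0 and r > 0:
            stats.chars_compared += 1
            if not chars_match(qc[q - 1], rc[r - 1]):
                break
            q -= 1
            r -= 1
            stats.extension_steps += 1
        qpos = end - (r - q)
        while end < len_r and qpos < len_q:
            stats.chars_compared += 1
            if not chars_match(qc[qpos], rc[end]):
                break
            end += 1
            qpos += 1
            stats.extension_steps += 1
        if end - r >= min_len:
            out.append(Seed(q, r, end - r))

    out.sort(key=lambda s: (s.delta, s.q))
    return out
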