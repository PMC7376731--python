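"""Brute-force definitional implementations, used as test-time ground truth.

Everything here is written to be obviously correct rather than fast:
MEM enumeration straight from the definition (maximal runs of matching
characters along each diagonal of the reference x query plane), SMEM and
maximal-spanning filters as literal all-pairs / per-position scans, and the
extend-purge strategy — extend every fixed-size seed independently, then
purge duplicates — as the baseline the merge-extend construction is
compared against.  The oracles refuse inputs with ``|Q| * |R| > 10**7`` to
prevent accidental production use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seed_model import DNA_ALPHABET, Seed, Sequence, chars_match

_SIZE_GUARD = 10**7


def _encode(seq: Sequence, bad_start: int, bad_step: int) -> np.ndarray:
    """Encode as small ints; characters outside {A,C,G,T} map to distinct
    negative codes so they never equal anything, not even themselves.  The
    two sequences of a comparison must use disjoint bad-code spaces
    (different ``bad_start``/``bad_step`` parities)."""
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    arr = np.empty(len(seq), dtype=np.int64)
    bad = bad_start
    for i, ch in enumerate(seq.chars):
        if ch in codes:
            arr[i] = codes[ch]
        else:
            arr[i] = bad
            bad -= bad_step
    return arr


def all_mems_bruteforce(Q: Sequence, R: Sequence) -> list[Seed]:
    """Every MEM of (Q, R), straight from the definition.

    For each matching position pair (y on Q, x on R), the MEM through it is
    the maximal run of equal characters along the diagonal ``x - y``;
    enumerating the maximal runs of every diagonal yields each MEM exactly
    once, duplicate-free by construction.
    """
    if len(Q) * len(R) > _SIZE_GUARD:
        raise ValueError("oracle size guard: |Q| * |R| must be <= 10^7")
    q_arr = _encode(Q, bad_start=-1, bad_step=2)  # odd bad codes
    r_arr = _encode(R, bad_start=-2, bad_step=2)  # even bad codes
    mems: list[Seed] = []
    for d in range(-(len(Q) - 1), len(R)):
        q0 = max(0, -d)
        r0 = q0 + d
        length = min(len(Q) - q0, len(R) - r0)
        if length <= 0:
            continue
        eq = q_arr[q0 : q0 + length] == r_arr[r0 : r0 + length]
        # maximal runs of True
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for s, e in zip(run_starts, run_ends):
            mems.append(Seed(q0 + int(s), r0 + int(s), int(e - s)))
    return mems


def smems_bruteforce(mems: list[Seed]) -> list[Seed]:
    """SMEMs by the all-pairs enclosure test."""
    out = []
    for s in mems:
        enclosed = any(
            t is not s
            and t.q <= s.q
            and s.q_end <= t.q_end
            and (t.q < s.q or s.q_end < t.q_end)
            for t in mems
        )
        if not enclosed:
            out.append(s)
    return out


def maxspan_bruteforce(mems: list[Seed]) -> list[Seed]:
    """Maximal spanning seeds by a literal per-query-position scan: keep a
    seed iff some query position of it is covered by no strictly longer
    seed."""
    out = []
    for s in mems:
        for p in range(s.q, s.q_end):
            if not any(t.l > s.l and t.q <= p < t.q_end for t in mems):
                out.append(s)
                break
    return out


@dataclass
class ExtendPurgeResult:
    """MEMs plus the work counters that make the strategies comparable as
    operation counts."""

    mems: list[Seed]
    extension_steps: int  # successful 1-nt advances over all seeds
    duplicates_purged: int

    @property
    def total_work(self) -> int:
        return self.extension_steps + self.duplicates_purged


def extend_purge_baseline(Q: Sequence, R: Sequence, seeds: list[Seed]) -> ExtendPurgeResult:
    """The extend-purge strategy: maximally extend every fixed-size seed
    independently in both directions, then delete duplicate (q, r, l)
    triples.

    Produces the same MEM set as the merge-extend construction on the same
    input, but a MEM containing several input seeds is discovered once per
    seed, and every such seed walks the full distance to the MEM's
    endpoints — the counters quantify that redundancy.
    """
    qc, rc = Q.chars, R.chars
    len_q, len_r = len(qc), len(rc)
    steps = 0
    seen: dict[tuple[int, int, int], Seed] = {}
    duplicates = 0
    for s in seeds:
        q, r, end = s.q, s.r, s.r_end
        while q > 0 and r > 0 and chars_match(qc[q - 1], rc[r - 1]):
            q -= 1
            r -= 1
            steps += 1
        qpos = end - (r - q)
        while end < len_r and qpos < len_q and chars_match(qc[qpos], rc[end]):
            end += 1
            qpos += 1
            steps += 1
        key = (q, r, end - r)
        if key in seen:
            duplicates += 1
        else:
            seen[key] = Seed(*key)
    return ExtendPurgeResult(
        mems=list(seen.values()), extension_steps=steps, duplicates_purged=duplicates
    )
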