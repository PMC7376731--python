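"""Correctness-rate metric and seed-set accounting.

For a read with known origin interval ``I`` on the reference and a seed set
``S``, the correctness rate is ``CR = n / |S|`` where ``n`` is the number of
nucleotides of ``I`` covered by at least one seed of ``S``.  It measures the
average number of correctly placed nucleotides a single seed contributes:
coverage (rather than summed seed length) avoids rewarding stacks of
overlapping seeds, and the denominator penalizes seed sets bloated with
mis-placed seeds.

A seed counts as *correct* if its reference interval intersects ``I`` (seeds
may legitimately overhang the origin's edges after maximal extension), and
as *incorrect* otherwise; seeds on a different contig than ``I`` are always
incorrect.  Note the metric cannot distinguish seeds inside ``I`` that
belong to the true alignment from coincidental ones — a limitation inherent
to knowing only the origin interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as PySequence

from . import indexing, merge_extend, seed_filters
from .seed_model import Seed, Sequence


@dataclass(frozen=True)
class OriginInterval:
    """The reference interval a read was sampled from (0-based, half-open)."""

    ref_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"origin interval needs start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CrReport:
    """Correctness-rate accounting for one read and one seed set."""

    n: int  # nucleotides of I covered by >= 1 seed
    set_size: int  # |S|
    cr: float  # n / |S|
    n_correct: int  # seeds whose reference interval intersects I
    n_incorrect: int


def correctness_rate(
    S: PySequence[Seed],
    I: OriginInterval,
    seed_ref_ids: Optional[PySequence[str]] = None,
) -> CrReport:
    """Compute the correctness rate of seed set ``S`` for origin ``I``.

    ``seed_ref_ids`` optionally gives, per seed, the contig its reference
    coordinates refer to; seeds on contigs other than ``I.ref_id`` are
    incorrect and never contribute coverage.  An empty ``S`` has an
    undefined rate and raises.
    """
    if len(S) == 0:
        raise ValueError("correctness rate is undefined for an empty seed set")
    if seed_ref_ids is not None and len(seed_ref_ids) != len(S):
        raise ValueError("seed_ref_ids must parallel S")

    intervals: list[tuple[int, int]] = []
    n_correct = 0
    for i, s in enumerate(S):
        on_contig = seed_ref_ids is None or seed_ref_ids[i] == I.ref_id
        lo, hi = max(s.r, I.start), min(s.r_end, I.end)
        if on_contig and lo < hi:
            n_correct += 1
            intervals.append((lo, hi))
    # coverage: union length of the clipped intervals
    intervals.sort()
    n = 0
    cur_lo, cur_hi = None, None
    for lo, hi in intervals:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                n += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        n += cur_hi - cur_lo
    return CrReport(
        n=n,
        set_size=len(S),
        cr=n / len(S),
        n_correct=n_correct,
        n_incorrect=len(S) - n_correct,
    )


@dataclass(frozen=True)
class SeedSetAccount:
    """Correct/incorrect counts (and CR when defined) for one seed set."""

    name: str
    n_correct: int
    n_incorrect: int
    cr: Optional[float]

    @property
    def size(self) -> int:
        return self.n_correct + self.n_incorrect


def _account(name: str, seeds: list[Seed], I: OriginInterval) -> SeedSetAccount:
    if not seeds:
        return SeedSetAccount(name, 0, 0, None)
    rep = correctness_rate(seeds, I)
    return SeedSetAccount(name, rep.n_correct, rep.n_incorrect, rep.cr)


def hierarchy_counts(
    Q: Sequence,
    R: Sequence,
    I: OriginInterval,
    k: int,
    w: int,
    occ_threshold: Optional[int] = None,
    check_chains: bool = True,
) -> dict[str, SeedSetAccount]:
    """Correct/incorrect seed counts for the five-set hierarchy on one read.

    Computes k-mer seeds, (w, k)-minimizer seeds, and — from the minimizer
    seeds — MEMs, SMEMs and maximal spanning seeds, the variable-size sets
    restricted to length >= w + k - 1 (the regime in which every MEM is
    recoverable from the minimizers).  For each set, a seed is correct iff
    its reference interval intersects ``I``.  Since minimizer seeds are a
    subset of k-mer seeds, MEMs merge minimizer seeds, and the filters
    select subsets of the MEMs, both counts are non-increasing along
    k-mers >= minimizers >= MEMs >= SMEMs >= maximal spanning seeds; with
    ``check_chains=True`` (default) both chains are asserted.
    """
    full_idx = indexing.build_index(R, k=k, scheme="full", occ_threshold=occ_threshold)
    kmer_seeds = indexing.lookup_seeds(Q, full_idx)
    mini_idx = indexing.build_index(
        R, k=k, scheme="minimizer", m_or_w=w, occ_threshold=occ_threshold
    )
    mini_seeds = indexing.lookup_seeds(Q, mini_idx)
    params = merge_extend.MergeParams(k=k, m=w)  # min_out_len = w + k - 1
    mems = merge_extend.merge_and_extend(Q, R, mini_seeds, params)
    smems = seed_filters.filter_smems(mems)
    maxspan = seed_filters.filter_max_spanning(mems)

    table = {
        "kmer": _account("kmer", kmer_seeds, I),
        "minimizer": _account("minimizer", mini_seeds, I),
        "mem": _account("mem", mems, I),
        "smem": _account("smem", smems, I),
        "max_spanning": _account("max_spanning", maxspan, I),
    }
    if check_chains:
        names = ["kmer", "minimizer", "mem", "smem", "max_spanning"]
        for a, b in zip(names, names[1:]):
            if table[a].n_correct < table[b].n_correct:
                raise AssertionError(f"correct-count chain violated: {a} < {b}")
            if table[a].n_incorrect < table[b].n_incorrect:
                raise AssertionError(f"incorrect-count chain violated: {a} < {b}")
    return table
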