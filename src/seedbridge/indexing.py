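"""Fixed-size seed indexes over a reference sequence.

Three sampling schemes are supported for the reference side:

``full``
    every k-mer of the reference (step size 1);
``m-step``
    fixed sampling — only k-mers starting at positions divisible by ``m``;
``minimizer``
    (w, k)-minimizers — per window of ``w`` consecutive k-mer start
    positions, the k-mer(s) minimal under a total order on k-length words.

All schemes store their selected positions in a hash table mapping k-length
words to ascending reference positions.  An optional occurrence filter
removes every bucket holding strictly more reference positions than a
threshold, the standard way aligners suppress seeds from repetitive regions.
Query lookup pairs every query k-mer (the query side is never sampled) with
every surviving reference position of the same word, yielding the fixed-size
seed set that feeds the merge-extend MEM construction.

Both sampling schemes bound the gap between adjacent selected positions:
m-step sampling by construction, minimizers because every window of ``w``
consecutive positions contains a selected one.  That bound (``m`` resp.
``w``) is the sampling distance the merge-extend algorithm needs to close.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Union

from .seed_model import DNA_ALPHABET, PositionedKmer, Seed, Sequence

Scheme = Literal["full", "m-step", "minimizer"]

# Fixed multiplier of the splitmix64 finalizer; documented so that index
# dumps are reproducible across runs and machines.
_MIX_CONST_1 = 0xBF58476D1CE4E5B9
_MIX_CONST_2 = 0x94D049BB133111EB
_MASK64 = (1 << 64) - 1

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pack_2bit(word: str) -> int:
    v = 0
    for ch in word:
        v = (v << 2) | _BASE_CODE[ch]
    return v


def _splitmix64(x: int) -> int:
    x &= _MASK64
    x = ((x ^ (x >> 30)) * _MIX_CONST_1) & _MASK64
    x = ((x ^ (x >> 27)) * _MIX_CONST_2) & _MASK64
    return x ^ (x >> 31)


def hash_order(word: str) -> tuple[int, str]:
    """Default minimizer order: invertible 64-bit mix of the 2-bit-packed
    word, with the word itself as a deterministic tie-break.

    A mixing hash decorrelates the order from sequence composition (plain
    lexicographic order over-selects A-rich k-mers); the tie-break keeps the
    order total on words longer than 32 nt.
    """
    return (_splitmix64(_pack_2bit(word)), word)


def lex_order(word: str) -> str:
    """Plain lexicographic order — convenient for hand-checkable examples."""
    return word


ORDERS: dict[str, Callable[[str], object]] = {"hash": hash_order, "lex": lex_order}


def enumerate_kmers(W: Sequence, k: int) -> list[PositionedKmer]:
    """All positioned k-mers of ``W`` in ascending start position.

    K-mers containing any character outside {A,C,G,T} are omitted (such
    characters never match anything, so they can never seed).  A word
    shorter than ``k`` yields an empty list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    chars = W.chars
    out: list[PositionedKmer] = []
    # track the most recent invalid character to skip windows cheaply
    last_bad = -1
    for i, ch in enumerate(chars):
        if ch not in DNA_ALPHABET:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            out.append(PositionedKmer(start, chars[start : start + k]))
    return out


def sample_mstep(kmers: list[PositionedKmer], m: int) -> list[PositionedKmer]:
    """Fixed sampling: keep exactly the k-mers with start position divisible
    by ``m``, preserving order."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return [km for km in kmers if km.x % m == 0]


def select_minimizers(
    W: Sequence,
    w: int,
    k: int,
    order: Union[str, Callable[[str], object]] = "hash",
) -> list[PositionedKmer]:
    """(w, k)-minimizers of ``W``.

    For every window of ``w`` consecutive k-mer start positions, all
    positions whose word attains the window minimum under ``order`` are
    selected; the result is the deduplicated union over windows, ascending
    by position.  Selecting *all* tied minima (rather than, say, the
    leftmost) preserves the two guarantees the downstream proofs rely on:
    adjacent selected positions differ by at most ``w``, and any two words
    sharing a substring of length >= w + k - 1 share a selected k-mer at the
    homologous offset.

    Windows are taken over the positions of valid (ambiguity-free) k-mers;
    a word shorter than ``w + k - 1`` yields no complete window and hence an
    empty list.
    """
    if w < 1 or k < 1:
        raise ValueError(f"w and k must be >= 1, got w={w}, k={k}")
    if isinstance(order, str):
        order = ORDERS[order]
    kmers = enumerate_kmers(W, k)
    if len(W) < w + k - 1:
        return []
    keys = [order(km.word) for km in kmers]
    selected: set[int] = set()
    # windows of w consecutive k-mer start positions; k-mers omitted for
    # ambiguity leave their window slot empty
    by_pos = {km.x: i for i, km in enumerate(kmers)}
    n_pos = len(W) - k + 1
    for w_start in range(0, n_pos - w + 1):
        idxs = [by_pos[p] for p in range(w_start, w_start + w) if p in by_pos]
        if not idxs:
            continue
        best = min(keys[i] for i in idxs)
        for i in idxs:
            if keys[i] == best:
                selected.add(i)
    return [kmers[i] for i in sorted(selected, key=lambda i: kmers[i].x)]


@dataclass
class KmerIndex:
    """Hash table from k-length words to ascending reference start positions.

    ``purged_words`` records exactly the words whose pre-filter bucket size
    exceeded ``occ_threshold``; their buckets are removed entirely.
    """

    k: int
    scheme: Scheme
    ref_id: str
    m_or_w: Optional[int] = None
    occ_threshold: Optional[int] = None
    buckets: dict[str, list[int]] = field(default_factory=dict)
    purged_words: set[str] = field(default_factory=set)

    @property
    def sampling_distance(self) -> int:
        """Maximal distance between adjacent sampled reference positions on a
        fully matching stretch: ``m`` for m-step, ``w`` for minimizers, 1 for
        the full index."""
        return 1 if self.scheme == "full" else int(self.m_or_w)  # type: ignore[arg-type]


def apply_occurrence_filter(idx: KmerIndex, occ_threshold: int) -> None:
    """Remove every bucket with strictly more than ``occ_threshold`` entries,
    recording the removed words."""
    purged = [w for w, positions in idx.buckets.items() if len(positions) > occ_threshold]
    for w in purged:
        del idx.buckets[w]
        idx.purged_words.add(w)
    idx.occ_threshold = occ_threshold


def build_index(
    R: Sequence,
    k: int,
    scheme: Scheme = "full",
    m_or_w: Optional[int] = None,
    occ_threshold: Optional[int] = None,
    order: Union[str, Callable[[str], object]] = "hash",
) -> KmerIndex:
    """Build a k-mer index over reference ``R`` under the given scheme, then
    apply the occurrence filter (if any) to the hash-table buckets."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if scheme == "full":
        kmers = enumerate_kmers(R, k)
        m_or_w = None
    elif scheme == "m-step":
        if m_or_w is None or m_or_w < 1:
            raise ValueError(f"m-step scheme needs step size m >= 1, got {m_or_w}")
        kmers = sample_mstep(enumerate_kmers(R, k), m_or_w)
    elif scheme == "minimizer":
        if m_or_w is None or m_or_w < 1:
            raise ValueError(f"minimizer scheme needs window size w >= 1, got {m_or_w}")
        kmers = select_minimizers(R, m_or_w, k, order=order)
    else:
        raise ValueError(f"unknown scheme: {scheme}")

    idx = KmerIndex(k=k, scheme=scheme, ref_id=R.id, m_or_w=m_or_w)
    for km in kmers:
        idx.buckets.setdefault(km.word, []).append(km.x)
    if occ_threshold is not None:
        apply_occurrence_filter(idx, occ_threshold)
    return idx


def lookup_seeds(
    Q: Sequence,
    idx: KmerIndex,
    query_minimizers: bool = False,
    order: Union[str, Callable[[str], object]] = "hash",
) -> list[Seed]:
    """Fixed-size seeds between ``Q`` and the indexed reference.

    Every query k-mer is looked up — sampling applies to the reference side
    only, which is what makes every sufficiently long MEM recoverable.  With
    ``query_minimizers=True`` (minimizer indexes only) the query side is
    additionally restricted to its own minimizers, the practical sketching
    mode of minimizer aligners; the recoverability guarantee then requires
    both sides to share a minimizer, which holds for matches of length
    >= w + k - 1 only when both sequences use the same order.
    """
    if query_minimizers:
        if idx.scheme != "minimizer":
            raise ValueError("query_minimizers applies to minimizer indexes only")
        q_kmers = select_minimizers(Q, int(idx.m_or_w), idx.k, order=order)
    else:
        q_kmers = enumerate_kmers(Q, idx.k)
    seeds: list[Seed] = []
    buckets = idx.buckets
    for km in q_kmers:
        positions = buckets.get(km.word)
        if positions:
            for r in positions:
                seeds.append(Seed(km.x, r, idx.k))
    return seeds


# ---------------------------------------------------------------------------
# persistence: JSON-lines dump with a version header


_INDEX_FORMAT_VERSION = 1


def save_index(idx: KmerIndex, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        header = {
            "format": "seedbridge-index",
            "version": _INDEX_FORMAT_VERSION,
            "k": idx.k,
            "scheme": idx.scheme,
            "ref_id": idx.ref_id,
            "m_or_w": idx.m_or_w,
            "occ_threshold": idx.occ_threshold,
            "purged_words": sorted(idx.purged_words),
        }
        fh.write(json.dumps(header) + "\n")
        for word in sorted(idx.buckets):
            fh.write(json.dumps([word] + idx.buckets[word]) + "\n")


def load_index(path: Union[str, Path]) -> KmerIndex:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "seedbridge-index":
            raise ValueError(f"{path} is not a seedbridge index dump")
        if header["version"] != _INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format version {header['version']}")
        idx = KmerIndex(
            k=header["k"],
            scheme=header["scheme"],
            ref_id=header["ref_id"],
            m_or_w=header["m_or_w"],
            occ_threshold=header["occ_threshold"],
            purged_words=set(header["purged_words"]),
        )
        for line in fh:
            if not line.strip():
                continue
            row = json.loads(line)
            idx.buckets[row[0]] = [int(x) for x in row[1:]]
    return idx
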