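"""Core domain types and geometric predicates on seeds.

A *seed* is an exact match between a query ``Q`` and a reference ``R``,
written as a triple ``(q, r, l)``: start position on the query, start
position on the reference, and length.  All coordinates in this package are
0-based and all intervals half-open, so a seed occupies ``Q[q, q+l)`` on the
query and ``R[r, r+l)`` on the reference.

The *delta value* of a seed is ``r - q``.  Seeds with equal delta lie on the
same diagonal of the reference x query plane; two seeds on one diagonal
whose reference intervals overlap or touch are *attached* and describe one
contiguous region of equivalence — the basis of the merge-extend MEM
construction in :mod:`seedbridge.merge_extend`.

Only the four-letter DNA alphabet ``{A, C, G, T}`` participates in matching.
Other characters (e.g. ``N``) are representable in sequences but never match
any character, including themselves, so ambiguity runs can never produce
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

SEED_TSV_HEADER = ("query_id", "ref_id", "q", "r", "l", "delta")


def chars_match(a: str, b: str) -> bool:
    """True iff ``a`` and ``b`` are the same character of {A,C,G,T}.

    Characters outside the alphabet never match, not even themselves.
    """
    return a == b and a in DNA_ALPHABET


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over {A,C,G,T} plus ambiguity characters.

    Positions are 0-based; substring access uses half-open slices.
    """

    id: str
    chars: str

    def __len__(self) -> int:
        return len(self.chars)

    def __getitem__(self, item: Union[int, slice]) -> str:
        return self.chars[item]

    def __iter__(self) -> Iterator[str]:
        return iter(self.chars)


@dataclass(frozen=True, order=True)
class Seed:
    """An exact match ``(q, r, l)`` between a query and a reference.

    Value object: equality and ordering are componentwise on ``(q, r, l)``.
    """

    q: int
    r: int
    l: int

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError(f"seed length must be >= 1, got {self.l}")
        if self.q < 0 or self.r < 0:
            raise ValueError(f"seed start positions must be >= 0, got ({self.q}, {self.r})")

    @property
    def delta(self) -> int:
        return self.r - self.q

    @property
    def q_end(self) -> int:
        """One past the last query position, i.e. the query interval is [q, q_end)."""
        return self.q + self.l

    @property
    def r_end(self) -> int:
        return self.r + self.l


@dataclass(frozen=True)
class PositionedKmer:
    """A k-length word together with its start offset on its source word."""

    x: int
    word: str


def delta(s: Seed) -> int:
    """Delta value ``r - q`` of a seed (may be negative)."""
    return s.r - s.q


def attached(s1: Seed, s2: Seed) -> bool:
    """True iff the seeds share a delta value and their reference intervals
    overlap or touch (one starting exactly where the other ends counts)."""
    if delta(s1) != delta(s2):
        return False
    return s1.r <= s2.r_end and s2.r <= s1.r_end


def encloses(outer: Seed, inner: Seed) -> bool:
    """True iff ``outer``'s query interval strictly contains ``inner``'s.

    Seeds spanning the same query interval (necessarily with different
    reference intervals) never enclose each other; both survive SMEM
    filtering.
    """
    if outer == inner:
        return False
    if not (outer.q <= inner.q and inner.q_end <= outer.q_end):
        return False
    # equal query intervals do not enclose
    return outer.q < inner.q or inner.q_end < outer.q_end


def merge_span(a: Seed, b: Seed) -> Seed:
    """The seed spanning two attached seeds on their shared diagonal."""
    if not attached(a, b):
        raise ValueError("can only merge attached seeds")
    q = min(a.q, b.q)
    r = min(a.r, b.r)
    end = max(a.r_end, b.r_end)
    return Seed(q, r, end - r)


def seed_is_exact_match(s: Seed, Q: Sequence, R: Sequence) -> bool:
    """Check the defining property of a seed: Q<s> == R<s> character-for-
    character over the alphabet, within both sequence bounds."""
    if s.q_end > len(Q) or s.r_end > len(R):
        return False
    return all(chars_match(Q[s.q + i], R[s.r + i]) for i in range(s.l))


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: Union[str, Path]) -> list[Sequence]:
    """Read a (multi-record) FASTA file.

    Sequences are forced to uppercase; the description after the first
    whitespace of the header line is ignored.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(Sequence(id=rec.id, chars=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[Sequence], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.chars), width):
                fh.write(s.chars[i : i + width] + "\n")


def write_seeds_tsv(
    rows: Iterable[tuple[str, str, Seed]],
    out: Union[str, Path, TextIO],
) -> None:
    """Write seeds as TSV with 0-based, half-open coordinates.

    Columns: ``query_id  ref_id  q  r  l  delta``.
    """

    def _write(fh: TextIO) -> None:
        fh.write("\t".join(SEED_TSV_HEADER) + "\n")
        for query_id, ref_id, s in rows:
            fh.write(f"{query_id}\t{ref_id}\t{s.q}\t{s.r}\t{s.l}\t{delta(s)}\n")

    if hasattr(out, "write"):
        _write(out)  # type: ignore[arg-type]
    else:
        with open(out, "w") as fh:
            _write(fh)


def read_seeds_tsv(path: Union[str, Path]) -> list[tuple[str, str, Seed]]:
    rows: list[tuple[str, str, Seed]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SEED_TSV_HEADER:
            raise ValueError(f"unexpected seed TSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            query_id, ref_id, q, r, l, _delta = line.rstrip("\n").split("\t")
            rows.append((query_id, ref_id, Seed(int(q), int(r), int(l))))
    return rows
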