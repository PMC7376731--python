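"""Synthetic references and error-bearing reads with recorded origins.

The generator stands in for long-read simulation on a real genome: an
i.i.d. uniform reference with optional planted repeats (needed to exercise
occurrence filters), and reads sampled uniformly from it with independent
per-base substitution, insertion and deletion errors.  Every read records
the reference interval it actually consumed, which is what the
correctness-rate metric evaluates seed sets against.

The default error rates (2% substitutions, 2% insertions, 1% deletions)
emulate a mid-quality long read — between error-free and raw
continuous-long-read quality; scale all three jointly to sweep the error
rate.  Defaults for lengths (100 kb reference, 1 kb reads) keep a full
simulate-seed-filter-evaluate round trip interactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .metrics import OriginInterval
from .seed_model import Sequence

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Configuration of one simulation run.  ``seed`` is mandatory state:
    every run is bit-reproducible from its config."""

    ref_len: int = 100_000
    read_len: int = 1_000
    n_reads: int = 100
    sub_rate: float = 0.02
    ins_rate: float = 0.02
    del_rate: float = 0.01
    repeat_spec: Optional[list[tuple[int, int]]] = None  # (motif length, copies)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0 + 1e-12:
            raise ValueError("sub_rate + ins_rate + del_rate must be < 1")
        if self.ref_len < 1:
            raise ValueError(f"ref_len must be >= 1, got {self.ref_len}")
        if self.read_len < 1:
            raise ValueError(f"read_len must be >= 1, got {self.read_len}")

    def scaled(self, factor: float) -> "SimConfig":
        """Copy with all three error rates multiplied by ``factor`` — the
        error-rate sweep knob."""
        return SimConfig(
            ref_len=self.ref_len,
            read_len=self.read_len,
            n_reads=self.n_reads,
            sub_rate=self.sub_rate * factor,
            ins_rate=self.ins_rate * factor,
            del_rate=self.del_rate * factor,
            repeat_spec=self.repeat_spec,
            seed=self.seed,
        )


def make_reference(cfg: SimConfig, ref_id: str = "ref") -> Sequence:
    """An i.i.d. uniform {A,C,G,T} reference with planted repeats.

    For each ``(motif_len, copies)`` entry of ``repeat_spec`` a random motif
    is written at ``copies`` random positions (dispersed repeats, possibly
    overlapping other sequence), so k-mers of the motif reach bucket sizes
    that trigger occurrence filtering.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    chars = rng.choice(_BASES, size=cfg.ref_len)
    if cfg.repeat_spec:
        for motif_len, copies in cfg.repeat_spec:
            if motif_len > cfg.ref_len:
                raise ValueError("repeat motif longer than the reference")
            motif = rng.choice(_BASES, size=motif_len)
            starts = rng.integers(0, cfg.ref_len - motif_len + 1, size=copies)
            for s in starts:
                chars[s : s + motif_len] = motif
    return Sequence(id=ref_id, chars="".join(chars))


def sample_reads(R: Sequence, cfg: SimConfig) -> list[tuple[Sequence, OriginInterval]]:
    """Sample reads with per-base errors, recording origin intervals.

    Each read consumes ``read_len`` consecutive reference bases starting at
    a uniform position.  Per consumed base: it is deleted with probability
    ``del_rate``; otherwise emitted, substituted by a different base with
    probability ``sub_rate``; before each consumed base a uniformly random
    base is inserted with probability ``ins_rate``.  The origin interval is
    exactly the consumed reference span.
    """
    if cfg.read_len > len(R):
        raise ValueError("read_len exceeds reference length")
    rng = np.random.default_rng([cfg.seed, 1])
    out: list[tuple[Sequence, OriginInterval]] = []
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(cfg.n_reads):
        start = int(rng.integers(0, len(R) - cfg.read_len + 1))
        end = start + cfg.read_len
        pieces: list[str] = []
        u = rng.random(size=(cfg.read_len, 2))
        ins_bases = rng.integers(0, 4, size=cfg.read_len)
        sub_shift = rng.integers(1, 4, size=cfg.read_len)
        for j, pos in enumerate(range(start, end)):
            if u[j, 0] < cfg.ins_rate:
                pieces.append(str(_BASES[ins_bases[j]]))
            if u[j, 1] < cfg.del_rate:
                continue
            ch = R[pos]
            if u[j, 1] < cfg.del_rate + cfg.sub_rate and ch in base_index:
                # substitute by a different base
                ch = str(_BASES[(base_index[ch] + sub_shift[j]) % 4])
            pieces.append(ch)
        read = Sequence(id=f"read{i}", chars="".join(pieces))
        out.append((read, OriginInterval(ref_id=R.id, start=start, end=end)))
    return out
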