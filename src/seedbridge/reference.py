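"""Definitional reference implementations, re-exported under one namespace.

These are the brute-force oracles (obviously correct, test-scale only) plus
the extend-purge baseline strategy; see :mod:`seedbridge.oracle`.
"""

from .oracle import (
    ExtendPurgeResult,
    all_mems_bruteforce,
    extend_purge_baseline,
    maxspan_bruteforce,
    smems_bruteforce,
)

__all__ = [
    "ExtendPurgeResult",
    "all_mems_bruteforce",
    "extend_purge_baseline",
    "maxspan_bruteforce",
    "smems_bruteforce",
]
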