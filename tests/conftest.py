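import random

import pytest
from hypothesis import HealthCheck, settings

from seedbridge import Sequence

settings.register_profile(
    "seedbridge",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seedbridge")


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def random_pair(rng: random.Random, max_q: int = 60, max_r: int = 120, plant: bool = True):
    """A random (Q, R) pair, optionally with a shared planted substring so
    that long MEMs actually occur."""
    Q = list(random_dna(rng, rng.randint(10, max_q)))
    R = list(random_dna(rng, rng.randint(20, max_r)))
    if plant and rng.random() < 0.8:
        n = rng.randint(5, min(len(Q), len(R), 25))
        sub = random_dna(rng, n)
        qs = rng.randint(0, len(Q) - n)
        rs = rng.randint(0, len(R) - n)
        Q[qs : qs + n] = sub
        R[rs : rs + n] = sub
    return Sequence("q", "".join(Q)), Sequence("r", "".join(R))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260928)
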