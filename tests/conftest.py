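import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_string(rng, seq, rate):
    """Substitution-only divergence with the mutated positions returned."""
    out = list(seq)
    positions = np.flatnonzero(rng.random(len(seq)) < rate)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out), positions


@pytest.fixture
def two_sample_toy():
    """Two tiny samples sharing one identical transcript."""
    from crossclean import SampleAssembly

    g = np.random.default_rng(7)
    shared = random_dna(g, 120)
    a = SampleAssembly.from_records(
        "A", [("a1", shared), ("a2", random_dna(g, 150))]
    )
    b = SampleAssembly.from_records(
        "B", [("b1", shared), ("b2", random_dna(g, 90))]
    )
    return a, b
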