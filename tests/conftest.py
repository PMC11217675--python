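"""Shared fixtures: small synthetic datasets reused across test modules.

Session-scoped so the Markov generation and feature computation run once.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ucnescan import features, synthetic
from ucnescan.seqio import MaskedSequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """50 i.i.d.-uniform sequences of 200-1000 nt (no N), for oracle checks."""
    out = []
    for i in range(50):
        n = int(rng.integers(200, 1001))
        out.append(MaskedSequence(
            id=f"r{i}", residues="".join(rng.choice(list("ACGT"), n))))
    return out


@pytest.fixture(scope="session")
def small_benchmark():
    """Default-spec benchmark, 150 sequences per class."""
    return synthetic.make_benchmark(n_per_class=150, seed=7)


@pytest.fixture(scope="session")
def small_table(small_benchmark):
    return features.build_feature_table(
        small_benchmark.positives, small_benchmark.negatives)
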