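import numpy as np
import pytest
from hypothesis import settings

from nitriminer import load_motifs, load_observed_matches

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def patterns():
    return load_motifs()


@pytest.fixture(scope="session")
def patterns_by_id(patterns):
    return {p.id: p for p in patterns}


@pytest.fixture(scope="session")
def snippets():
    return load_observed_matches()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_protein(rng, length: int, name: str = "rand") -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
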