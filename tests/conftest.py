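import numpy as np
import pytest

from tmspath import RunConfig
from tmspath.fixtures import FamilySpec, evolve_family, make_founder, make_protein

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def fast_config() -> RunConfig:
    """Small shuffle count for unit tests; statistics tested elsewhere."""
    return RunConfig(shuffles=50, seed=7)


@pytest.fixture
def fourfour():
    """One 4+4 (duplicated 4-TMS unit) protein with planted topology."""
    return make_protein("4+4", seed=3)


@pytest.fixture
def duplicated_member():
    """A protein built by exact duplication of a 4-TMS founder (no drift)."""
    spec = FamilySpec(events=("duplicate",), n_members=1, mutation_prob=0.0,
                      indel_prob=0.0, seed=11, label="DUP")
    return evolve_family(spec)[0]


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA20, size=length))
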