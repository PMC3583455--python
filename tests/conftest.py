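import numpy as np
import pytest

from gsalloc import (
    assign_architecture,
    default_genome,
    f1_individual,
    make_dh_population,
)


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def small_genome():
    from gsalloc import build_genome

    return build_genome(2, [120.0, 80.0], 50)


@pytest.fixture(scope="session")
def architecture(genome):
    return assign_architecture(genome, rng=np.random.default_rng(101))


@pytest.fixture(scope="session")
def dh_population(genome):
    f1 = f1_individual(genome)
    return make_dh_population(f1, 300, genome, np.random.default_rng(102))
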