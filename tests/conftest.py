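import dendropy
import numpy as np
import pytest

from endovir.simulate.config import SimulationConfig
from endovir.simulate.genome import simulate_genome_bundle


@pytest.fixture(scope="session")
def four_taxon_tree() -> dendropy.Tree:
    t = dendropy.Tree.get(
        data="((A:1.2,B:0.7):0.5,(C:0.9,D:1.1):0.3);", schema="newick"
    )
    t.is_rooted = True
    return t


@pytest.fixture(scope="session")
def small_bundle():
    """One default synthetic genome bundle shared across read-only tests."""
    return simulate_genome_bundle(SimulationConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
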