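import numpy as np
import pytest

from symphy import synth
from symphy.phylo import parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_four_tree():
    return parse_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture(scope="session")
def medium_tree():
    """Shared 60-tip ultrametric birth-death tree (400 Myr root age)."""
    return synth.sim_tree(60, seed=42)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(123))
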