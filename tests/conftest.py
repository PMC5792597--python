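import numpy as np
import pytest

import cetadiv as cd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_tip_tree():
    return cd.PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_tree():
    return cd.PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def study_bundle():
    """One full synthetic study at the default (study-scale) conditions."""
    return cd.simulate_study(cd.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def tree100():
    return cd.simulate_yule_tree(100, 1.0, seed=11)
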