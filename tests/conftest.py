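import pytest
from hypothesis import settings

import phylobias as pb

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

FIG2 = "((A:2.5,B:2.5):5.0,(C:2.5,D:2.5):5.0);"


@pytest.fixture
def fig2_tree():
    """Four-taxon worked example: two cherries splitting 2.5 Mya, crown 7.5 Mya."""
    return pb.parse_newick(FIG2)


@pytest.fixture
def fig2_record():
    return pb.make_fig2_fixture()


@pytest.fixture(scope="session")
def yule_tree():
    """A seeded pure-birth tree of moderate size for property checks."""
    tree = pb.simulate_birth_death(pb.SimParams(lam=0.1, t_max=40, seed=11))
    assert tree is not None and tree.n_tips >= 30
    return tree


@pytest.fixture(scope="session")
def bd_tree():
    """A seeded birth-death tree with extinct lineages."""
    tree = pb.simulate_birth_death(pb.SimParams(lam=0.12, mu=0.05, t_max=40, seed=23))
    assert tree is not None
    return tree
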