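import pytest
from hypothesis import settings

from dtlrec.ccp import observe_trees

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from dtlrec.model import DTLRates
from dtlrec.phylo import index_species_tree

NWK8 = "(((A,B),(C,D)),((E,F),(G,H)));"
NWK16 = ("((((A,B),(C,D)),((E,F),(G,H))),"
         "(((I,J),(K,L)),((M,N),(O,P))));")


@pytest.fixture(scope="session")
def tree1():
    return index_species_tree("A;")


@pytest.fixture(scope="session")
def tree2():
    return index_species_tree("(A,B);")


@pytest.fixture(scope="session")
def tree3():
    return index_species_tree("((A,B),C);")


@pytest.fixture(scope="session")
def tree6():
    return index_species_tree("(((A,B),C),((D,E),F));")


@pytest.fixture(scope="session")
def tree8():
    return index_species_tree(NWK8)


@pytest.fixture(scope="session")
def tree16():
    return index_species_tree(NWK16)


@pytest.fixture(scope="session")
def single_copy_ccp3():
    """Congruent single-copy 3-gene family on ((A,B),C)."""
    return observe_trees(
        "sc3", ["((A_g,B_g),C_g);"],
        {"A_g": "A", "B_g": "B", "C_g": "C"}, mode="rooted",
    )


@pytest.fixture(scope="session")
def mid_rates():
    return DTLRates(0.08, 0.12, 0.15)
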