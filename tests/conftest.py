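import pytest

from haloflux.formats_io import species_tree_from_string


@pytest.fixture
def four_leaf_tree():
    """((A,B)n1,(C,D)n2)root with labelled internal nodes."""
    return species_tree_from_string("((A,B)n1,(C,D)n2)root;")


@pytest.fixture
def narrative_tree():
    """Six-leaf tree mirroring the halophile-ancestor node names."""
    nwk = (
        "((M1,M2)MMI,((Ha1,Ha2)LHaCA,(Hi1,Hi2)LHiCA)LHHCA)LMHHCA;"
    )
    return species_tree_from_string(nwk)
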