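import pytest

from phylostrat import parse_species_tree


@pytest.fixture
def four_leaf_tree():
    """((A,B)AB,(C,D)CD)Root with ages AB=100, CD=150, Root=500."""
    return parse_species_tree(
        "((A,B)AB,(C,D)CD)Root;", ages={"AB": 100, "CD": 150, "Root": 500}
    )


@pytest.fixture
def chain_tree():
    """Caterpillar tree (((A,B)AB,C)ABC,D)Root for multi-level path tests."""
    return parse_species_tree(
        "(((A,B)AB,C)ABC,D)Root;", ages={"AB": 50, "ABC": 200, "Root": 600}
    )
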