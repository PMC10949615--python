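import pytest

from condiga.synthetic import default_design, simulate_community
from condiga.taxonomy import TaxonomyTree


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """root -> Bacteria -> family F -> genera G1,G2 -> species/strains."""
    nodes = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        3: (2, "phylum", "P"),
        4: (3, "class", "C"),
        5: (4, "order", "O"),
        10: (5, "family", "F"),
        11: (10, "genus", "G1"),
        12: (10, "genus", "G2"),
        101: (11, "species", "SpA"),
        102: (11, "species", "SpB"),
        103: (12, "species", "SpC"),
        1011: (101, "strain", "SpA str. 1"),
    }
    return TaxonomyTree(nodes=nodes, root_id=1)


@pytest.fixture(scope="session")
def community():
    """The stock 12-species + 40-decoy community with a 2% chimera rate."""
    return simulate_community(default_design(n_decoys=40, seed=42, chimera_rate=0.02))


@pytest.fixture(scope="session")
def small_community():
    """A light community for fast per-stage tests."""
    return simulate_community(default_design(n_decoys=5, seed=7, chimera_rate=0.0))
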