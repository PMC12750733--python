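import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from duinet import synthetic


@pytest.fixture(scope="session")
def species_tree_30():
    """30-taxon ultrametric species tree with six foreground clades."""
    return synthetic.make_species_tree(30, 6, [2, 2, 2, 2, 1, 1], seed=1)


@pytest.fixture(scope="session")
def species_tree_36():
    return synthetic.make_species_tree(36, 6, [2, 2, 2, 2, 1, 1], seed=1)


@pytest.fixture(scope="session")
def mixed_10taxon_tree(species_tree_36):
    """10-taxon subtree with 4 foreground and 6 background tips."""
    taxa = sorted(species_tree_36.foreground)[:4] + sorted(
        species_tree_36.background
    )[:6]
    return species_tree_36.prune_to(taxa)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
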