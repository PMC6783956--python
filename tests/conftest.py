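import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from elevagrad import CommunityMatrix, parse_newick


@pytest.fixture
def cherry_tree():
    return parse_newick("(A:1,B:2);")


@pytest.fixture
def three_taxon_tree():
    # d(A,B)=2, d(A,C)=d(B,C)=4
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_matrix():
    counts = pd.DataFrame(
        {"A": [2, 0], "B": [1, 3], "C": [1, 5]},
        index=["p1", "p2"],
        dtype=np.int64,
    )
    elev = pd.Series([2500.0, 3000.0], index=["p1", "p2"])
    return CommunityMatrix(counts, elev)


def random_instance(seed: int, n_min: int = 4, n_max: int = 8):
    """A random small tree plus a random plot abundance map on it."""
    from elevagrad import simulate_tree

    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    tree = simulate_tree(n, seed=seed)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    k = int(rng.integers(2, n + 1))
    present = rng.choice(labels, size=k, replace=False)
    abund = {str(sp): int(rng.integers(1, 12)) for sp in present}
    return tree, abund
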