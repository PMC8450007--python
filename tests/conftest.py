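import numpy as np
import pytest

from phylostab import (
    StrategySpec,
    SyntheticTreeSetConfig,
    TaxonSet,
    generate_treeset,
    parse_newick,
)
from phylostab.synthetic import random_unrooted_tree


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((A,B)95,(C,D));")


@pytest.fixture
def abcd_taxa():
    return TaxonSet(["A", "B", "C", "D"])


@pytest.fixture
def random_tree():
    """Factory: random unrooted binary tree over n generated labels."""

    def make(n, seed=0):
        rng = np.random.default_rng(seed)
        return random_unrooted_tree([f"L{i:03d}" for i in range(n)], rng)

    return make


@pytest.fixture
def small_treeset():
    """3 strategies x 4 trees over 9 taxa in 3 groups, with ground truth."""
    cfg = SyntheticTreeSetConfig(
        n_taxa=9,
        group_sizes=(3, 3, 3),
        strategies=(
            StrategySpec("tight", 4, nni_moves=0, jitter_prob=0.0, kappa=200.0),
            StrategySpec("mid", 4, nni_moves=1, jitter_prob=0.1, kappa=50.0),
            StrategySpec("loose", 4, nni_moves=2, jitter_prob=0.3, kappa=10.0),
        ),
        seed=42,
    )
    return generate_treeset(cfg)
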