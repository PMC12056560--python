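import numpy as np
import pytest

from mothtails.trees import Phylogeny


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — the canonical worked example."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Factory for a star phylogeny of n tips with unit branch lengths."""

    def make(n: int, depth: float = 1.0) -> Phylogeny:
        parent = np.concatenate([[-1], np.zeros(n, dtype=int)])
        lengths = np.concatenate([[0.0], np.full(n, depth)])
        labels = [None] + [f"t{i}" for i in range(n)]
        return Phylogeny(parent=parent, edge_length=lengths, labels=labels)

    return make


@pytest.fixture
def random_tree():
    """Factory for a random ultrametric pure-birth tree."""
    from mothtails.synth import simulate_tree

    def make(n: int, seed: int) -> Phylogeny:
        return simulate_tree(n, birth_rate=1.0, death_rate=0.0, seed=seed)

    return make
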