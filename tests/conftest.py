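import numpy as np
import pytest

from phyloring.fixtures import FixtureSpec, random_tree


def make_tree_corpus(n, seed=42, min_leaves=2, max_leaves=64, branch_lengths=False):
    """Deterministic suite of random trees with varying size."""
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n):
        spec = FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_leaves=int(rng.integers(min_leaves, max_leaves + 1)),
            branch_lengths=branch_lengths,
        )
        trees.append(random_tree(spec))
    return trees


@pytest.fixture
def tree_corpus():
    return make_tree_corpus


@pytest.fixture
def chain_tree():
    """R -> A -> B -> C, handy for wildcard-resolution checks."""
    from phyloring.tree import Tree, TreeNode

    c = TreeNode(name="C")
    b = TreeNode(name="B", children=[c])
    a = TreeNode(name="A", children=[b])
    return Tree(TreeNode(name="R", children=[a]))
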