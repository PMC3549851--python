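import random

import pytest
from hypothesis import settings

from tripletdist import RootedBinaryTree, TreeSimConfig, random_binary_tree

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_pair(n: int, seed: int, models=("yule", "uniform", "caterpillar")):
    """Two random trees on the same n labels (independent shapes/seeds)."""
    rng = random.Random(seed)
    m1, m2 = rng.choice(models), rng.choice(models)
    t1 = random_binary_tree(TreeSimConfig(n, m1, rng.randrange(2**30)))
    t2 = random_binary_tree(TreeSimConfig(n, m2, rng.randrange(2**30)))
    return t1, t2


def shuffle_children(tree: RootedBinaryTree, seed: int) -> RootedBinaryTree:
    """Copy of the tree with each node's child order flipped at random."""
    rng = random.Random(seed)
    children = [
        tuple(reversed(c)) if c and rng.random() < 0.5 else tuple(c)
        for c in tree.children
    ]
    return RootedBinaryTree(tree.parent, children, tree.labels, root=tree.root)


@pytest.fixture
def pair_factory():
    return make_pair
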