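"""Deterministic binary-tree simulation for tests and benchmarks.

Four shape models:

``yule``
    Pure-birth process: starting from one lineage, repeatedly pick a
    uniformly random extant leaf and split it.  Produces moderately
    balanced trees (expected depth O(log n)).
``uniform``
    Random coalescent join order: repeatedly merge two uniformly chosen
    subtrees.  Uniform over labeled histories; somewhat less balanced
    than Yule.
``caterpillar``
    Maximally unbalanced comb — the recursion-depth and HDT-balance
    stress case.
``balanced``
    Recursive halving — the most balanced shape achievable.

All generators are seeded explicitly per call via :class:`random.Random`
(no global state), so the same configuration reproduces the same Newick
string on every platform.  Leaves are labeled ``L0 .. L<n-1>``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .treeio import RootedBinaryTree

__all__ = [
    "TreeSimConfig",
    "MODELS",
    "random_binary_tree",
    "yule_tree",
    "uniform_tree",
    "caterpillar",
    "balanced_tree",
    "perturb_labels",
]

MODELS = ("yule", "uniform", "caterpillar", "balanced")


@dataclass(frozen=True)
class TreeSimConfig:
    """Simulation request: leaf count, shape model and seed."""

    n: int
    model: str = "yule"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"need at least one leaf, got n={self.n}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")


def _finish(parent: list[int], children: list[list[int]], root: int) -> RootedBinaryTree:
    labels: list[str | None] = [None] * len(parent)
    tree = RootedBinaryTree(parent, children, labels, root=root)
    for i, v in enumerate(tree.leaves()):
        tree.labels[v] = f"L{i}"
    return tree


def yule_tree(n: int, seed: int = 0) -> RootedBinaryTree:
    """Pure-birth (Yule) tree: split a uniformly random leaf n-1 times."""
    rng = random.Random(seed)
    parent = [-1]
    children: list[list[int]] = [[]]
    leaves = [0]
    for _ in range(n - 1):
        i = rng.randrange(len(leaves))
        u = leaves[i]
        a, b = len(parent), len(parent) + 1
        parent.extend((u, u))
        children[u] = [a, b]
        children.extend(([], []))
        leaves[i] = a
        leaves.append(b)
    return _finish(parent, children, 0)


def uniform_tree(n: int, seed: int = 0) -> RootedBinaryTree:
    """Random coalescent: repeatedly join two uniformly chosen subtrees."""
    rng = random.Random(seed)
    parent = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    roots = list(range(n))
    while len(roots) > 1:
        i, j = rng.sample(range(len(roots)), 2)
        a, b = roots[i], roots[j]
        u = len(parent)
        parent.append(-1)
        children.append([a, b])
        parent[a] = u
        parent[b] = u
        # replace the smaller index, drop the larger (order-stable removal)
        i, j = (i, j) if i < j else (j, i)
        roots[i] = u
        roots.pop(j)
    return _finish(parent, children, roots[0])


def caterpillar(n: int) -> RootedBinaryTree:
    """Fully unbalanced comb; the deepest leaf sits at depth n-1."""
    if n < 1:
        raise ValueError(f"need at least one leaf, got n={n}")
    if n == 1:
        return _finish([-1], [[]], 0)
    # nodes 0..n-1 leaves; n..2n-2 internal, built upward from the cherry
    parent = [-1] * (2 * n - 1)
    children: list[list[int]] = [[] for _ in range(2 * n - 1)]
    spine = n  # cherry over leaves 0, 1
    children[spine] = [0, 1]
    parent[0] = parent[1] = spine
    for k in range(2, n):
        node = n + k - 1
        children[node] = [spine, k]
        parent[spine] = node
        parent[k] = node
        spine = node
    return _finish(parent, children, spine)


def balanced_tree(n: int) -> RootedBinaryTree:
    """Recursively halved tree (depth ceil(log2 n))."""
    if n < 1:
        raise ValueError(f"need at least one leaf, got n={n}")
    parent = [-1]
    children: list[list[int]] = [[]]
    sizes = {0: n}
    stack = [0]
    while stack:
        v = stack.pop()
        sz = sizes.pop(v)
        if sz == 1:
            continue
        a, b = len(parent), len(parent) + 1
        parent.extend((v, v))
        children[v] = [a, b]
        children.extend(([], []))
        sizes[a] = (sz + 1) // 2
        sizes[b] = sz // 2
        stack.extend((a, b))
    return _finish(parent, children, 0)


def random_binary_tree(config: TreeSimConfig) -> RootedBinaryTree:
    """Generate the tree described by ``config`` (bit-reproducible)."""
    if config.model == "yule":
        return yule_tree(config.n, config.seed)
    if config.model == "uniform":
        return uniform_tree(config.n, config.seed)
    if config.model == "caterpillar":
        return caterpillar(config.n)
    return balanced_tree(config.n)


def perturb_labels(tree: RootedBinaryTree, k: int, seed: int = 0) -> RootedBinaryTree:
    """Copy of ``tree`` with ``k`` random leaf-label pair swaps.

    The shape is untouched, so the result differs from the original only
    in which labels sit where — a cheap way to span a range of triplet
    distances from a reference tree.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    rng = random.Random(seed)
    out = RootedBinaryTree(tree.parent, tree.children, tree.labels, root=tree.root)
    leaf_nodes = out.leaves()
    if len(leaf_nodes) >= 2:
        for _ in range(k):
            i, j = rng.sample(range(len(leaf_nodes)), 2)
            u, v = leaf_nodes[i], leaf_nodes[j]
            out.labels[u], out.labels[v] = out.labels[v], out.labels[u]
    return out
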