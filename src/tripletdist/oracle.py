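"""Reference semantics for the triplet distance.

A *triplet* is an unordered set of three leaves; in a rooted binary tree it
induces exactly one resolved topology, identified by the pair of leaves
whose lowest common ancestor lies strictly below the LCA of all three.
``Shared(T1, T2)`` counts the triplets inducing the same topology in both
trees, and the triplet distance is ``C(n,3) - Shared``.

Two independent reference algorithms live here:

* :func:`brute_force_shared` — O(n^3) enumeration of all 3-subsets.
* :func:`quadratic_shared` — for each internal node ``v`` of the first
  tree, color one child subtree red and the other blue and count, in the
  second tree, the triplets *compatible* with that coloring (two leaves of
  one color joined below a node, one leaf of the other color elsewhere
  under it).  Because the triplet sets rooted at distinct nodes partition
  all triplets, the per-node counts sum to ``Shared``.

Both are oracles for the sub-quadratic algorithm in :mod:`tripletdist.hdt`
/ :mod:`tripletdist.distance`.
"""

from __future__ import annotations

from enum import IntEnum
from itertools import combinations
from typing import Mapping, Sequence

from .treeio import LeafMap, RootedBinaryTree, align_leaf_ids, leaf_ranges

__all__ = [
    "Color",
    "triplet_topology",
    "brute_force_shared",
    "count_compatible",
    "quadratic_shared",
]


class Color(IntEnum):
    """Leaf color used to encode the triplets rooted at one node."""

    NONE = 0
    RED = 1
    BLUE = 2


def _choose2(k: int) -> int:
    """C(k, 2), defined as 0 for k < 2."""
    return k * (k - 1) // 2


def _as_color_list(coloring, n: int) -> list[int]:
    if isinstance(coloring, Mapping):
        out = [int(Color.NONE)] * n
        for leaf, col in coloring.items():
            out[leaf] = int(col)
        return out
    if len(coloring) != n:
        raise ValueError(f"coloring covers {len(coloring)} of {n} leaves")
    return [int(c) for c in coloring]


def _depths(tree: RootedBinaryTree) -> list[int]:
    depth = [0] * tree.n_nodes
    for v in tree.preorder():
        for c in tree.children[v]:
            depth[c] = depth[v] + 1
    return depth


def _lca(u: int, v: int, parent: Sequence[int], depth: Sequence[int]) -> int:
    while depth[u] > depth[v]:
        u = parent[u]
    while depth[v] > depth[u]:
        v = parent[v]
    while u != v:
        u = parent[u]
        v = parent[v]
    return u


def _leaf_nodes(tree: RootedBinaryTree, leaf_map: LeafMap) -> list[int]:
    """leaf id -> node index."""
    node_ids = leaf_map.node_ids(tree)
    out = [-1] * len(leaf_map)
    for v, lid in enumerate(node_ids):
        if lid >= 0:
            out[lid] = v
    if any(v < 0 for v in out):
        raise LookupError("leaf map does not cover all ids for this tree")
    return out


def triplet_topology(
    tree: RootedBinaryTree,
    a: int,
    b: int,
    c: int,
    leaf_map: LeafMap | None = None,
) -> frozenset[int]:
    """Resolved pair of the triplet ``{a, b, c}`` (leaf ids) in ``tree``.

    Returns the 2-subset whose LCA is a proper descendant of the LCA of all
    three leaves — the pair the tree "groups together".
    """
    if len({a, b, c}) != 3:
        raise ValueError("triplet leaves must be distinct")
    lm = leaf_map if leaf_map is not None else LeafMap.from_tree(tree)
    nodes = _leaf_nodes(tree, lm)
    for leaf in (a, b, c):
        if not 0 <= leaf < len(nodes):
            raise LookupError(f"unknown leaf id {leaf}")
    depth = _depths(tree)
    parent = tree.parent
    best_pair: tuple[int, int] | None = None
    best_depth = -1
    for p, q in combinations((a, b, c), 2):
        d = depth[_lca(nodes[p], nodes[q], parent, depth)]
        if d > best_depth:
            best_depth = d
            best_pair = (p, q)
    return frozenset(best_pair)


def _pair_lca_depths(tree: RootedBinaryTree, leaf_map: LeafMap) -> list[list[int]]:
    """Depth of LCA(leaf i, leaf j) for all leaf-id pairs (O(n^2 h))."""
    n = len(leaf_map)
    nodes = _leaf_nodes(tree, leaf_map)
    depth = _depths(tree)
    parent = tree.parent
    table = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = depth[_lca(nodes[i], nodes[j], parent, depth)]
            table[i][j] = d
            table[j][i] = d
    return table


def _resolved_pair_index(dij: int, dik: int, djk: int) -> int:
    """0, 1, 2 for resolved pair (i,j), (i,k), (j,k): the deepest LCA wins."""
    if dij > dik and dij > djk:
        return 0
    if dik > djk:
        return 1
    return 2


def brute_force_shared(
    t1: RootedBinaryTree,
    t2: RootedBinaryTree,
    leaf_map: LeafMap | None = None,
) -> int:
    """Number of 3-subsets inducing the same topology in both trees, by
    direct enumeration of all ``C(n, 3)`` triplets."""
    lm = leaf_map if leaf_map is not None else align_leaf_ids(t1, t2)
    n = len(lm)
    if n < 3:
        return 0
    d1 = _pair_lca_depths(t1, lm)
    d2 = _pair_lca_depths(t2, lm)
    shared = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                p1 = _resolved_pair_index(d1[i][j], d1[i][k], d1[j][k])
                p2 = _resolved_pair_index(d2[i][j], d2[i][k], d2[j][k])
                if p1 == p2:
                    shared += 1
    return shared


def count_compatible(
    t2: RootedBinaryTree,
    coloring,
    leaf_map: LeafMap | None = None,
) -> int:
    """Triplets of ``t2`` compatible with a red/blue/none leaf coloring.

    A triplet is compatible when two of its leaves share one color, the
    third carries the other color, and ``t2`` joins the two same-colored
    leaves below the triplet's LCA.  Summing, per internal node ``u`` with
    child subtrees ``x`` and ``y`` holding ``x(r), x(b), y(r), y(b)``
    red/blue leaves::

        C(x(b),2)*y(r) + C(y(b),2)*x(r) + C(y(r),2)*x(b) + C(x(r),2)*y(b)

    over all internal ``u`` gives the count in one bottom-up pass.
    ``coloring`` is a sequence indexed by leaf id (or a mapping) of
    :class:`Color` values.
    """
    lm = leaf_map if leaf_map is not None else LeafMap.from_tree(t2)
    colors = _as_color_list(coloring, len(lm))
    node_ids = lm.node_ids(t2)
    nn = t2.n_nodes
    red = [0] * nn
    blue = [0] * nn
    total = 0
    for v in t2.postorder():
        kids = t2.children[v]
        if not kids:
            col = colors[node_ids[v]]
            red[v] = 1 if col == Color.RED else 0
            blue[v] = 1 if col == Color.BLUE else 0
            continue
        x, y = kids
        xr, xb, yr, yb = red[x], blue[x], red[y], blue[y]
        total += (
            _choose2(xb) * yr
            + _choose2(yb) * xr
            + _choose2(yr) * xb
            + _choose2(xr) * yb
        )
        red[v] = xr + yr
        blue[v] = xb + yb
    return total


def quadratic_shared(
    t1: RootedBinaryTree,
    t2: RootedBinaryTree,
    leaf_map: LeafMap | None = None,
) -> int:
    """O(n^2) reference: explicit coloring per internal node of ``t1``.

    For each internal ``v`` of ``t1`` the first child subtree is colored
    RED and the second BLUE (all other leaves NONE; the formula is
    color-symmetric so the assignment is arbitrary but fixed), and the
    compatible triplets of ``t2`` are counted.  The totals sum to
    ``Shared(t1, t2)`` because the triplet sets rooted at distinct nodes
    partition all triplets.
    """
    lm = leaf_map if leaf_map is not None else align_leaf_ids(t1, t2)
    n = len(lm)
    if n < 3:
        return 0
    node_ids1 = lm.node_ids(t1)
    leaf_seq, lo, hi = leaf_ranges(t1, node_ids1)
    coloring = [int(Color.NONE)] * n
    shared = 0
    for v in range(t1.n_nodes):
        kids = t1.children[v]
        if not kids:
            continue
        c1, c2 = kids
        for i in range(lo[c1], hi[c1]):
            coloring[leaf_seq[i]] = int(Color.RED)
        for i in range(lo[c2], hi[c2]):
            coloring[leaf_seq[i]] = int(Color.BLUE)
        shared += count_compatible(t2, coloring, lm)
        for i in range(lo[v], hi[v]):
            coloring[leaf_seq[i]] = int(Color.NONE)
    return shared
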