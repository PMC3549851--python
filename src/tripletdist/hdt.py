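"""Hierarchical decomposition tree (HDT) with compatible-triplet counters.

The HDT is a balanced binary tree built over the *counted* tree: every HDT
node ("component") covers a connected piece of the underlying tree with at
most two boundary edges (one up toward the root, one down into a subtree).
Base components are single leaves (**L**) and single inner nodes (**I**);
composed components (**C**) arise by greedily contracting underlying-tree
edges, which shrinks the live edge list geometrically and yields
O(log n) height in O(n) total construction work.

Each component carries seven exact-integer tallies of the current red/blue
leaf coloring restricted to the component:

==========  ==========================================================
``R, B``    red / blue leaves in the component
``rr, bb``  same-color pairs lying in the *same* pendant subtree
            hanging off the component's spine (sum of C(r(i),2) etc.)
``rb``      red-below-blue cross-subtree pairs along the spine
``br``      blue-below-red cross-subtree pairs
``N``       compatible triplets entirely inside the component
==========  ==========================================================

A composed component's tallies are a constant-size function of its two
children's tallies, so recoloring one leaf updates only the leaf-to-root
HDT path (O(log n)), and the full count is read off the root in O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .oracle import Color, _as_color_list
from .treeio import LeafMap, RootedBinaryTree

__all__ = [
    "Counters",
    "ZERO_COUNTERS",
    "leaf_counters",
    "merge_counters",
    "IterationStats",
    "BuildStats",
    "HDT",
    "build_hdt",
    "set_leaf_color",
    "bulk_recolor",
    "root_count",
    "KIND_L",
    "KIND_I",
    "KIND_C",
    "CASE_A",
    "CASE_B",
]

KIND_L, KIND_I, KIND_C = 0, 1, 2
CASE_A, CASE_B = 0, 1  # spine-extension merge / inner-node capping merge


class Counters(NamedTuple):
    """The seven per-component tallies (all non-negative exact integers)."""

    R: int
    B: int
    rr: int
    bb: int
    rb: int
    br: int
    N: int


ZERO_COUNTERS = Counters(0, 0, 0, 0, 0, 0, 0)


def _c2(k: int) -> int:
    return k * (k - 1) // 2


def leaf_counters(color: Color) -> Counters:
    """Counters of a leaf (L) component under ``color``.

    Inner-node (I) components always carry :data:`ZERO_COUNTERS`.
    """
    if color == Color.RED:
        return Counters(1, 0, 0, 0, 0, 0, 0)
    if color == Color.BLUE:
        return Counters(0, 1, 0, 0, 0, 0, 0)
    return ZERO_COUNTERS


def merge_counters(bottom: Counters, top: Counters, case: str) -> Counters:
    """Combine child counters into the composed component's counters.

    ``case="a"``: the component below (``bottom``) extends the spine of the
    component above (``top``); cross-subtree pair counts pick up the new
    below/above combinations and ``N`` gains every way of completing a
    same-color pair on one side with an opposite-color leaf on the other::

        N = N1 + N2 + C(R1,2)*B2 + C(B1,2)*R2
            + rr2*B1 + bb2*R1 + R1*rb2 + B1*br2

    ``case="b"``: an inner node caps a down-closed component; the whole
    bottom collapses into a single pendant subtree of the new component
    (``rr = C(R1,2)``, ``bb = C(B1,2)``, no cross pairs), and no leaves are
    added so ``N`` is unchanged.
    """
    r1, b1, rr1, bb1, rb1, br1, n1 = bottom
    if case == "b" or case == CASE_B:
        return Counters(r1, b1, _c2(r1), _c2(b1), 0, 0, n1)
    r2, b2, rr2, bb2, rb2, br2, n2 = top
    return Counters(
        r1 + r2,
        b1 + b2,
        rr1 + rr2,
        bb1 + bb2,
        rb2 + rb1 + r1 * b2,
        br2 + br1 + b1 * r2,
        n1 + n2
        + _c2(r1) * b2
        + _c2(b1) * r2
        + rr2 * b1
        + bb2 * r1
        + r1 * rb2
        + b1 * br2,
    )


@dataclass(frozen=True)
class IterationStats:
    """One greedy contraction pass over the live edge list."""

    edges: int  # live edges at the start of the pass
    contractible: int  # edges satisfying a merge case against start-of-pass state
    contracted: int  # edges actually contracted


@dataclass
class BuildStats:
    iterations: list[IterationStats] = field(default_factory=list)
    height: int = 0  # max leaf-to-root HDT path length, in edges
    n_components: int = 0


class HDT:
    """Hierarchical decomposition tree of a rooted binary tree.

    Components are stored in flat parallel arrays in creation order, which
    is automatically bottom-up (children precede parents), so a single
    index sweep re-derives every counter.  Component indices ``< n_nodes``
    are the base L/I components (index = underlying node index).
    """

    def __init__(self, tree: RootedBinaryTree, leaf_map: LeafMap | None = None):
        self.tree = tree
        self.leaf_map = leaf_map if leaf_map is not None else LeafMap.from_tree(tree)
        self.n_leaves = len(self.leaf_map)
        self._build()
        ncomp = len(self._kind)
        self.kind = np.array(self._kind, dtype=np.int8)
        self.parent = np.array(self._par, dtype=np.int64)
        self.bottom = np.array(self._bot, dtype=np.int64)
        self.top = np.array(self._top, dtype=np.int64)
        self.case = np.array(self._case, dtype=np.int8)
        self.down_closed = np.array(self._dcl, dtype=bool)
        self.comp_leaf_id = np.array(self._comp_leaf_id, dtype=np.int64)
        self.leaf_comp = np.array(self._leaf_comp, dtype=np.int64)
        del self._kind, self._par, self._bot, self._top
        del self._case, self._dcl, self._comp_leaf_id, self._leaf_comp
        self.R = np.zeros(ncomp, dtype=np.int64)
        self.B = np.zeros(ncomp, dtype=np.int64)
        self.rr = np.zeros(ncomp, dtype=np.int64)
        self.bb = np.zeros(ncomp, dtype=np.int64)
        self.rb = np.zeros(ncomp, dtype=np.int64)
        self.br = np.zeros(ncomp, dtype=np.int64)
        self.N = np.zeros(ncomp, dtype=np.int64)

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        tree = self.tree
        nn = tree.n_nodes
        node_ids = self.leaf_map.node_ids(tree)
        self._kind = [KIND_L if not tree.children[v] else KIND_I for v in range(nn)]
        self._dcl = [k == KIND_L for k in self._kind]
        self._par = list(range(nn))  # self-pointer = "no parent yet"
        self._bot = [-1] * nn
        self._top = [-1] * nn
        self._case = [-1] * nn
        self._comp_leaf_id = list(node_ids)
        self._leaf_comp = [-1] * self.n_leaves
        for v in range(nn):
            if node_ids[v] >= 0:
                self._leaf_comp[node_ids[v]] = v

        # one edge per underlying tree edge, in preorder
        es: list[tuple[int, int]] = []
        for v in tree.preorder():
            for c in tree.children[v]:
                es.append((v, c))

        self.stats = BuildStats()
        while es:
            es = self._contract_once(es)
        self.root = len(self._kind) - 1 if nn > 1 else 0
        self._dcl[self.root] = True  # the root component is the whole tree
        self._par[self.root] = -1
        self.stats.n_components = len(self._kind)
        self.stats.height = self._compute_height()

    def _contractible(self, u: int, d: int) -> bool:
        if self._kind[u] == KIND_C and self._kind[d] != KIND_I:
            return True
        return self._kind[u] == KIND_I and self._dcl[d]

    def _contract_once(self, es: list[tuple[int, int]]) -> list[tuple[int, int]]:
        """One greedy pass: contract every edge whose endpoints are still
        unconsumed and match a merge case; return the deferred edges with
        endpoint references forwarded to the new components."""
        kind, dcl, par = self._kind, self._dcl, self._par
        contractible = sum(1 for u, d in es if self._contractible(u, d))
        nxt: list[tuple[int, int]] = []
        contracted = 0
        for u, d in es:
            if par[u] != u or par[d] != d:
                nxt.append((u, d))  # an endpoint was consumed this pass
                continue
            if kind[u] == KIND_C and kind[d] != KIND_I:
                case, down_closed = CASE_A, dcl[d]
            elif kind[u] == KIND_I and dcl[d]:
                case, down_closed = CASE_B, False
            else:
                nxt.append((u, d))  # no composition applies yet
                continue
            new = len(kind)
            kind.append(KIND_C)
            dcl.append(down_closed)
            par.append(new)
            self._bot.append(d)
            self._top.append(u)
            self._case.append(case)
            self._comp_leaf_id.append(-1)
            par[u] = new
            par[d] = new
            contracted += 1
        self.stats.iterations.append(
            IterationStats(len(es), contractible, contracted)
        )
        # forward deferred edges to freshly created parents (par[x] == x
        # still means "unconsumed", so this is a no-op for those)
        return [(par[u], par[d]) for u, d in nxt]

    def _compute_height(self) -> int:
        ncomp = len(self._kind)
        depth = [0] * ncomp
        for c in range(ncomp - 1, -1, -1):
            p = self._par[c]
            if p != -1:
                depth[c] = depth[p] + 1
        return max(
            (depth[c] for c in range(ncomp) if self._kind[c] != KIND_C),
            default=0,
        )

    # -- counter maintenance ----------------------------------------------

    @property
    def n_components(self) -> int:
        return int(self.kind.shape[0])

    def counters(self, comp: int) -> Counters:
        return Counters(
            int(self.R[comp]),
            int(self.B[comp]),
            int(self.rr[comp]),
            int(self.bb[comp]),
            int(self.rb[comp]),
            int(self.br[comp]),
            int(self.N[comp]),
        )

    def _recompute(self, c: int) -> None:
        b = self.bottom[c]
        t = self.top[c]
        r1 = self.R[b]
        b1 = self.B[b]
        if self.case[c] == CASE_B:
            self.R[c] = r1
            self.B[c] = b1
            self.rr[c] = r1 * (r1 - 1) // 2
            self.bb[c] = b1 * (b1 - 1) // 2
            self.rb[c] = 0
            self.br[c] = 0
            self.N[c] = self.N[b]
            return
        r2 = self.R[t]
        b2 = self.B[t]
        self.R[c] = r1 + r2
        self.B[c] = b1 + b2
        self.rr[c] = self.rr[b] + self.rr[t]
        self.bb[c] = self.bb[b] + self.bb[t]
        self.rb[c] = self.rb[t] + self.rb[b] + r1 * b2
        self.br[c] = self.br[t] + self.br[b] + b1 * r2
        self.N[c] = (
            self.N[b]
            + self.N[t]
            + (r1 * (r1 - 1) // 2) * b2
            + (b1 * (b1 - 1) // 2) * r2
            + self.rr[t] * b1
            + self.bb[t] * r1
            + r1 * self.rb[t]
            + b1 * self.br[t]
        )

    def set_leaf_color(self, leaf: int, color: Color) -> None:
        """Recolor one leaf and refresh counters along its HDT root path."""
        if not 0 <= leaf < self.n_leaves:
            raise LookupError(f"unknown leaf id {leaf}")
        c = int(self.leaf_comp[leaf])
        self.R[c] = 1 if color == Color.RED else 0
        self.B[c] = 1 if color == Color.BLUE else 0
        c = int(self.parent[c])
        while c != -1:
            self._recompute(c)
            c = int(self.parent[c])

    # sink protocol alias (see colorwalk.CountingSink)
    set_color = set_leaf_color

    def bulk_recolor(self, coloring) -> None:
        """Recompute every counter from a full coloring in one sweep."""
        colors = _as_color_list(coloring, self.n_leaves)
        kind = self.kind
        for c in range(self.n_components):
            k = kind[c]
            if k == KIND_C:
                self._recompute(c)
            elif k == KIND_L:
                col = colors[self.comp_leaf_id[c]]
                self.R[c] = 1 if col == Color.RED else 0
                self.B[c] = 1 if col == Color.BLUE else 0
            # I components stay all-zero

    def root_count(self) -> int:
        """Compatible triplets in the whole tree under the current coloring."""
        return int(self.N[self.root])

    count = root_count  # sink protocol alias


# -- spec-level functional surface ----------------------------------------


def build_hdt(t2: RootedBinaryTree, leaf_map: LeafMap | None = None) -> HDT:
    return HDT(t2, leaf_map)


def set_leaf_color(hdt: HDT, leaf: int, color: Color) -> None:
    hdt.set_leaf_color(leaf, color)


def bulk_recolor(hdt: HDT, coloring: Sequence[Color]) -> None:
    hdt.bulk_recolor(coloring)


def root_count(hdt: HDT) -> int:
    return hdt.root_count()
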