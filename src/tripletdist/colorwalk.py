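"""Smaller-half-trick traversal of the colored tree.

The first tree is traversed depth-first; at each internal node ``v`` only
the *smaller* child subtree ``S(v)`` is recolored, so each leaf is touched
O(log n) times overall (it is recolored a constant number of times per
ancestor whose smaller side contains it).  Two invariants drive the
scheduling: before ``v`` is processed its entire subtree is RED and the
rest of the tree uncolored, and after the recursion returns the whole tree
is uncolored.  At the harvest point (smaller side BLUE, larger side RED)
the sink's count equals the shared-triplet contribution of ``v``.

The sink is pluggable: the HDT provides O(log n) updates and O(1) counts,
while :class:`CompatibleTripletSink` recounts from scratch and serves as a
test oracle.
"""

from __future__ import annotations

from typing import NamedTuple, Protocol, runtime_checkable

from .oracle import Color, count_compatible
from .treeio import LeafMap, RootedBinaryTree, leaf_ranges

__all__ = [
    "NodeInfo",
    "CountingSink",
    "CompatibleTripletSink",
    "EventRecordingSink",
    "compute_node_info",
    "smaller_half_walk",
]


class NodeInfo(NamedTuple):
    """Per-internal-node sizes and child roles for the walk."""

    size: int  # leaves below the node
    smaller: int  # child with the fewer leaves (ties: first child)
    larger: int  # the other child


@runtime_checkable
class CountingSink(Protocol):
    """Consumer of leaf color changes that can report a triplet count."""

    def set_color(self, leaf: int, color: Color) -> None: ...

    def count(self) -> int: ...


def compute_node_info(tree: RootedBinaryTree) -> dict[int, NodeInfo]:
    """Subtree sizes and smaller/larger child per internal node.

    Equal-sized children tie-break to the first child as the smaller one.
    A single-leaf tree yields an empty map.
    """
    size = [0] * tree.n_nodes
    info: dict[int, NodeInfo] = {}
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            size[v] = 1
            continue
        a, b = kids
        size[v] = size[a] + size[b]
        if size[a] <= size[b]:
            info[v] = NodeInfo(size[v], a, b)
        else:
            info[v] = NodeInfo(size[v], b, a)
    return info


def smaller_half_walk(
    tree: RootedBinaryTree,
    sink: CountingSink,
    leaf_map: LeafMap | None = None,
) -> int:
    """Run the smaller-half traversal of ``tree``, harvesting ``sink.count()``
    once per internal node; returns the harvested total.

    The caller must have established the entry invariant: every leaf of
    ``tree`` currently shows RED in the sink.  On return every leaf has
    been set to NONE.  Traversal state is an explicit stack, so maximally
    unbalanced (caterpillar) trees do not exhaust Python's recursion limit.
    """
    lm = leaf_map if leaf_map is not None else LeafMap.from_tree(tree)
    node_ids = lm.node_ids(tree)
    leaf_seq, lo, hi = leaf_ranges(tree, node_ids)
    info = compute_node_info(tree)

    total = 0
    # (node, stage): stage 0 = steps 1-3 (count, then descend the larger
    # side), stage 1 = steps 4-5 (re-redden the smaller side, descend it).
    stack: list[tuple[int, int]] = [(tree.root, 0)]
    while stack:
        v, stage = stack.pop()
        if not tree.children[v]:
            sink.set_color(node_ids[v], Color.NONE)
            continue
        s = info[v].smaller
        if stage == 0:
            for i in range(lo[s], hi[s]):
                sink.set_color(leaf_seq[i], Color.BLUE)
            total += sink.count()
            for i in range(lo[s], hi[s]):
                sink.set_color(leaf_seq[i], Color.NONE)
            stack.append((v, 1))
            stack.append((info[v].larger, 0))
        else:
            for i in range(lo[s], hi[s]):
                sink.set_color(leaf_seq[i], Color.RED)
            stack.append((s, 0))
    return total


class CompatibleTripletSink:
    """Oracle sink: recounts compatible triplets of ``t2`` from scratch.

    O(n) per count — useful only for validating the walk and the HDT at
    small n.
    """

    def __init__(self, t2: RootedBinaryTree, leaf_map: LeafMap):
        self.t2 = t2
        self.leaf_map = leaf_map
        self.coloring = [Color.NONE] * len(leaf_map)

    def set_color(self, leaf: int, color: Color) -> None:
        self.coloring[leaf] = color

    def count(self) -> int:
        return count_compatible(self.t2, self.coloring, self.leaf_map)


class EventRecordingSink:
    """Wrap a sink, tallying ``set_color`` events and optional snapshots."""

    def __init__(self, inner: CountingSink, record_harvests: bool = False):
        self.inner = inner
        self.events = 0
        self.record_harvests = record_harvests
        self.harvest_colorings: list[dict[int, Color]] = []
        self._coloring: dict[int, Color] = {}

    def set_color(self, leaf: int, color: Color) -> None:
        self.events += 1
        if color == Color.NONE:
            self._coloring.pop(leaf, None)
        else:
            self._coloring[leaf] = color
        self.inner.set_color(leaf, color)

    def count(self) -> int:
        if self.record_harvests:
            self.harvest_colorings.append(dict(self._coloring))
        return self.inner.count()

    @property
    def colored_leaves(self) -> dict[int, Color]:
        return dict(self._coloring)
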