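"""Rooted binary trees: Newick parsing/writing and leaf-label alignment.

The triplet distance is purely topological, so trees are stored as bare
parent/children index arrays plus leaf labels.  Branch lengths, internal
node labels and Newick comments are accepted on input and discarded.
Multifurcating nodes are a hard error: the counting formulas used by the
distance algorithms assume every internal node has exactly two children.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import dendropy

__all__ = [
    "RootedBinaryTree",
    "LeafMap",
    "parse_newick",
    "write_newick",
    "align_leaf_ids",
    "read_newick_file",
    "leaf_ranges",
    "TreeError",
    "NewickSyntaxError",
    "NonBinaryTreeError",
    "DuplicateLeafLabelError",
    "EmptyTreeError",
    "LeafSetMismatchError",
]


class TreeError(ValueError):
    """Base class for tree input/validation errors."""


class NewickSyntaxError(TreeError):
    """Malformed Newick text (dendropy's message includes line/column)."""


class NonBinaryTreeError(TreeError):
    """A node with a number of children other than 0 or 2."""


class DuplicateLeafLabelError(TreeError):
    """Two leaves carry the same label (or a leaf is unlabeled)."""


class EmptyTreeError(TreeError):
    """No tree in the input."""


class LeafSetMismatchError(TreeError):
    """The two trees do not have identical leaf-label sets."""

    def __init__(self, only_in_first: Sequence[str], only_in_second: Sequence[str]):
        self.only_in_first = sorted(only_in_first)
        self.only_in_second = sorted(only_in_second)
        super().__init__(
            "leaf sets differ: only in first tree: %r; only in second tree: %r"
            % (self.only_in_first, self.only_in_second)
        )


class RootedBinaryTree:
    """A rooted binary tree over ``2n - 1`` nodes indexed ``0 .. 2n - 2``.

    Attributes
    ----------
    parent : list[int]
        Parent node index per node; ``-1`` for the root.
    children : list[tuple[int, ...]]
        Ordered child indices per node; ``()`` for leaves.  Child order is
        preserved exactly as parsed/constructed (the distance is invariant
        under it, but round-tripping is exact).
    labels : list[str | None]
        Leaf label per node; ``None`` on internal nodes.
    root : int
        Index of the root node.
    """

    __slots__ = ("parent", "children", "labels", "root", "_n_leaves")

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        labels: Sequence[str | None],
        root: int | None = None,
    ):
        self.parent = list(parent)
        self.children = [tuple(c) for c in children]
        self.labels = list(labels)
        self.root = self.parent.index(-1) if root is None else root
        self._n_leaves = sum(1 for c in self.children if not c)

    # -- basic structure ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of leaves."""
        return self._n_leaves

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def preorder(self) -> list[int]:
        """Node indices, parents before children, left child first."""
        out: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            for c in reversed(self.children[v]):
                stack.append(c)
        return out

    def postorder(self) -> list[int]:
        """Node indices with every child before its parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def leaves(self) -> list[int]:
        """Leaf node indices in left-to-right (Euler) order."""
        return [v for v in self.preorder() if not self.children[v]]

    def leaf_labels(self) -> set[str]:
        return {self.labels[v] for v in range(self.n_nodes) if not self.children[v]}

    def validate(self) -> None:
        """Assert all structural invariants; raise :class:`TreeError` otherwise."""
        nn = self.n_nodes
        roots = [v for v in range(nn) if self.parent[v] == -1]
        if len(roots) != 1 or roots[0] != self.root:
            raise TreeError("tree must have exactly one root")
        seen_labels: set[str] = set()
        n_leaves = 0
        for v in range(nn):
            kids = self.children[v]
            if len(kids) not in (0, 2):
                raise NonBinaryTreeError(
                    f"node {v} has {len(kids)} children; expected 0 or 2"
                )
            for c in kids:
                if self.parent[c] != v:
                    raise TreeError(f"parent/child mismatch at node {c}")
            if kids:
                if self.labels[v] is not None:
                    raise TreeError(f"internal node {v} carries a leaf label")
            else:
                n_leaves += 1
                lab = self.labels[v]
                if not lab:
                    raise DuplicateLeafLabelError(f"leaf {v} is unlabeled")
                if lab in seen_labels:
                    raise DuplicateLeafLabelError(f"duplicate leaf label {lab!r}")
                seen_labels.add(lab)
        if nn != 2 * n_leaves - 1:
            raise TreeError(
                f"node count {nn} != 2n-1 for n={n_leaves} leaves"
            )
        # reachability from the root
        if len(self.preorder()) != nn:
            raise TreeError("not all nodes reachable from the root")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RootedBinaryTree n={self.n}>"


class LeafMap:
    """Bijection leaf label -> integer id in ``[0, n)`` shared by two trees."""

    __slots__ = ("label_to_id",)

    def __init__(self, label_to_id: dict[str, int]):
        self.label_to_id = label_to_id

    @classmethod
    def from_tree(cls, tree: RootedBinaryTree) -> "LeafMap":
        labels = sorted(tree.leaf_labels())
        return cls({lab: i for i, lab in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.label_to_id)

    def __getitem__(self, label: str) -> int:
        return self.label_to_id[label]

    def __contains__(self, label: str) -> bool:
        return label in self.label_to_id

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self.label_to_id.items())

    def node_ids(self, tree: RootedBinaryTree) -> list[int]:
        """Per-node leaf id (``-1`` on internal nodes) for ``tree``."""
        out = [-1] * tree.n_nodes
        for v in range(tree.n_nodes):
            if not tree.children[v]:
                lab = tree.labels[v]
                if lab not in self.label_to_id:
                    raise LeafSetMismatchError([lab], [])
                out[v] = self.label_to_id[lab]
        return out


def parse_newick(text: str) -> RootedBinaryTree:
    """Parse one Newick statement into a :class:`RootedBinaryTree`.

    Branch lengths, internal labels and ``[...]`` comments are tolerated and
    discarded; quoted labels and underscores are preserved literally.

    Raises
    ------
    EmptyTreeError, NewickSyntaxError, NonBinaryTreeError,
    DuplicateLeafLabelError
    """
    if text is None or not text.strip():
        raise EmptyTreeError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except TreeError:
        raise
    except Exception as exc:
        if "Duplicate taxon" in str(exc):  # dendropy rejects these upstream
            raise DuplicateLeafLabelError(f"duplicate leaf label: {exc}") from exc
        raise NewickSyntaxError(f"malformed Newick: {exc}") from exc
    if dtree.seed_node is None:  # pragma: no cover - dendropy guards this
        raise EmptyTreeError("no tree found in input")

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    parent: list[int] = [-1] * len(dnodes)
    children: list[tuple[int, ...]] = [()] * len(dnodes)
    labels: list[str | None] = [None] * len(dnodes)
    for i, nd in enumerate(dnodes):
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            raise NonBinaryTreeError(
                f"non-binary node with {len(kids)} children; "
                "only strictly binary rooted trees are supported"
            )
        children[i] = tuple(index[id(k)] for k in kids)
        for k in kids:
            parent[index[id(k)]] = i
        if not kids:
            lab = nd.taxon.label if nd.taxon is not None else None
            if not lab:
                raise DuplicateLeafLabelError("unlabeled leaf in Newick input")
            labels[i] = lab
    tree = RootedBinaryTree(parent, children, labels, root=0)
    tree.validate()
    return tree


def read_newick_file(path) -> RootedBinaryTree:
    """Read a single Newick tree from a UTF-8 text file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


_SAFE_LABEL = frozenset(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-+|/#&*"
)


def _format_label(label: str) -> str:
    if label and all(ch in _SAFE_LABEL for ch in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: RootedBinaryTree) -> str:
    """Serialize a tree to Newick, preserving child order exactly."""
    out: list[str | None] = [None] * tree.n_nodes
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            out[v] = _format_label(tree.labels[v])
        else:
            out[v] = "(" + ",".join(out[c] for c in kids) + ")"
    return out[tree.root] + ";"


def align_leaf_ids(t1: RootedBinaryTree, t2: RootedBinaryTree) -> LeafMap:
    """Map the shared leaf-label set of two trees to ids ``0 .. n-1``.

    Raises :class:`LeafSetMismatchError` listing the symmetric difference
    when the label sets differ.
    """
    s1, s2 = t1.leaf_labels(), t2.leaf_labels()
    if s1 != s2:
        raise LeafSetMismatchError(sorted(s1 - s2), sorted(s2 - s1))
    return LeafMap({lab: i for i, lab in enumerate(sorted(s1))})


def leaf_ranges(
    tree: RootedBinaryTree, node_ids: Sequence[int]
) -> tuple[list[int], list[int], list[int]]:
    """Euler-tour leaf layout: ``(leaf_seq, lo, hi)``.

    ``leaf_seq`` lists leaf *ids* in left-to-right tree order; every node's
    descendant leaves occupy the contiguous slice ``leaf_seq[lo[v]:hi[v]]``.
    Used so that recoloring a whole subtree is a range scan.
    """
    nn = tree.n_nodes
    lo = [0] * nn
    hi = [0] * nn
    leaf_seq: list[int] = []
    post = tree.postorder()
    # positions assigned in preorder; ranges merged bottom-up
    pos = 0
    for v in tree.preorder():
        if not tree.children[v]:
            lo[v] = pos
            hi[v] = pos + 1
            leaf_seq.append(node_ids[v])
            pos += 1
    for v in post:
        kids = tree.children[v]
        if kids:
            lo[v] = min(lo[c] for c in kids)
            hi[v] = max(hi[c] for c in kids)
    return leaf_seq, lo, hi
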