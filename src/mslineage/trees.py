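"""Rooted lineage trees with branch lengths in cell divisions.

A lineage tree's root is the (putative) zygote; every edge carries a branch
length interpreted as a number of cell divisions, and each node has a depth
(divisions from the root).  Newick reading/writing is delegated to dendropy.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = ["Node", "LineageTree", "read_newick", "write_newick"]

_counter = itertools.count()


class Node:
    __slots__ = ("label", "parent", "children", "branch_length", "depth", "_uid")

    def __init__(
        self,
        label: str | None = None,
        branch_length: float = 0.0,
        children: Sequence["Node"] | None = None,
    ) -> None:
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.branch_length = branch_length
        self.depth = 0.0
        self._uid = next(_counter)
        for child in children or ():
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, bl={self.branch_length})"


class LineageTree:
    """Rooted (or temporarily unrooted) tree over sampled cells."""

    def __init__(self, root: Node, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        self.leaf_meta: dict[str, dict[str, str]] = {}

    # --- traversal --------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"no leaf labelled {label!r}")

    # --- depths -----------------------------------------------------------

    def assign_depths(self) -> None:
        """depth(child) = depth(parent) + branch_length, depth(root) = 0."""
        self.root.depth = 0.0
        for node in self.preorder():
            if node.parent is not None:
                node.depth = node.parent.depth + node.branch_length

    def leaf_depth(self, label: str) -> float:
        return self.find_leaf(label).depth

    # --- bipartitions -----------------------------------------------------

    def leafsets(self) -> dict[Node, frozenset[str]]:
        sets: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.label])
            else:
                acc: frozenset[str] = frozenset()
                for child in node.children:
                    acc |= sets[child]
                sets[node] = acc
        return sets

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each bipartition is canonicalized as the lexicographically smaller
        of the two sides so rooted and unrooted representations of the same
        topology compare equal.
        """
        all_leaves = frozenset(self.leaf_labels())
        sets = self.leafsets()
        out: set[frozenset[str]] = set()
        for node, below in sets.items():
            if node is self.root or node.parent is None:
                continue
            if len(below) < 2 or len(all_leaves - below) < 2:
                continue
            other = all_leaves - below
            out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return out

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        """True when ``labels`` are exactly the leaves under some node."""
        target = frozenset(labels)
        return any(s == target for s in self.leafsets().values())

    # --- rerooting --------------------------------------------------------

    def reroot_at(self, node: Node) -> None:
        """Reorient all edges so ``node`` becomes the root."""
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        orig_bl = {n._uid: n.branch_length for n in path}
        # reverse parent/child along the root path
        for child, parent in zip(path[:-1], path[1:]):
            parent.children.remove(child)
        for child, parent in zip(path[:-1], path[1:]):
            child.children.append(parent)
            parent.parent = child
            parent.branch_length = orig_bl[child._uid]
        node.parent = None
        node.branch_length = 0.0
        self.root = node
        self.rooted = True
        self.assign_depths()

    def copy(self) -> "LineageTree":
        mapping: dict[Node, Node] = {}
        for node in self.postorder():
            clone = Node(node.label, node.branch_length)
            clone.depth = node.depth
            for child in node.children:
                clone.add_child(mapping[child])
            mapping[node] = clone
        tree = LineageTree(mapping[self.root], rooted=self.rooted)
        tree.leaf_meta = {k: dict(v) for k, v in self.leaf_meta.items()}
        return tree

    # --- IO ---------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = _quote(node.label or "")
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner})" + (_quote(node.label) if node.label else "")
            if node.parent is not None:
                body += f":{node.branch_length:g}"
            return body

        return fmt(self.root) + ";"

    def write_depth_table(self, path: str | Path) -> None:
        lines = ["node\tdepth"]
        for i, node in enumerate(self.postorder()):
            name = node.label or f"internal_{i}"
            lines.append(f"{name}\t{node.depth:g}")
        Path(path).write_text("\n".join(lines) + "\n")


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> LineageTree:
    mapping: dict = {}
    for dnode in dtree.postorder_node_iter():
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, branch_length=float(dnode.edge.length or 0.0))
        for dchild in dnode.child_nodes():
            node.add_child(mapping[id(dchild)])
        mapping[id(dnode)] = node
    tree = LineageTree(mapping[id(dtree.seed_node)], rooted=True)
    tree.assign_depths()
    return tree


def read_newick(path: str | Path) -> LineageTree:
    """Read a Newick tree (branch lengths preserved, depths recomputed)."""
    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return _from_dendropy(dtree)


def write_newick(tree: LineageTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
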