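"""Rooted, dated trees with node ages in thousands of years before present (ka BP).

The tree is the central container of the package: tips are languages (extant at
age 0 or extinct at a fixed positive age), internal nodes are divergence events
whose ages are free parameters, and every branch has a duration (parent age
minus child age) plus a per-branch rate multiplier used by relaxed clocks.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional, Sequence

import dendropy

__all__ = ["Node", "TimeTree"]

AGE_TOL = 1e-9


class Node:
    """A node of a :class:`TimeTree`.

    Attributes
    ----------
    label : str or None
        Taxon name for tips; optional for internal nodes.
    age : float
        Node age in ka BP (0 = present).
    rate : float
        Multiplier of the clock rate on the branch above this node
        (ignored for the root).
    """

    __slots__ = ("label", "age", "rate", "parent", "children")

    def __init__(self, label: Optional[str] = None, age: float = 0.0,
                 rate: float = 1.0):
        self.label = label
        self.age = float(age)
        self.rate = float(rate)
        self.parent: Optional[Node] = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def duration(self) -> float:
        """Duration of the branch above this node, in ka."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, age={self.age:.4g})"


class TimeTree:
    """A rooted bifurcating tree with dated nodes."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
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

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def root_age(self) -> float:
        return self.root.age

    def total_branch_length(self) -> float:
        return sum(n.duration for n in self.postorder() if n.parent is not None)

    # ------------------------------------------------------------------
    # structure queries
    # ------------------------------------------------------------------
    def tip_set(self, node: Node) -> frozenset[str]:
        """Labels of the tips descending from ``node``."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def clades(self) -> dict[Node, frozenset[str]]:
        """Map every node to its descendant tip set (postorder-filled)."""
        sets: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.label])
            else:
                acc: frozenset[str] = frozenset()
                for c in node.children:
                    acc = acc | sets[c]
                sets[node] = acc
        return sets

    def find_tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise KeyError(f"no tip named {label!r}")

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = frozenset(labels)
        missing = want - frozenset(self.tip_labels)
        if missing:
            raise KeyError(f"unknown taxa: {sorted(missing)}")
        best = None
        for node, tipset in self.clades().items():
            if want <= tipset:
                if best is None or len(tipset) < len(self.tip_set(best)):
                    best = node
        assert best is not None
        return best

    def validate(self) -> None:
        """Raise ``ValueError`` on broken age ordering or non-binary nodes."""
        for node in self.postorder():
            if node.is_leaf:
                if node.age < -AGE_TOL:
                    raise ValueError(f"tip {node.label!r} has negative age")
                continue
            if len(node.children) != 2:
                raise ValueError("tree must be strictly bifurcating")
            for c in node.children:
                if node.age <= c.age - AGE_TOL:
                    raise ValueError(
                        f"parent age {node.age} not above child age {c.age}")

    # ------------------------------------------------------------------
    # copying
    # ------------------------------------------------------------------
    def copy(self) -> "TimeTree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.age, n.rate)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return TimeTree(clone(self.root))

    def map_copy(self) -> tuple["TimeTree", dict[Node, Node]]:
        """Copy returning the old-node -> new-node correspondence."""
        mapping: dict[Node, Node] = {}

        def clone(n: Node) -> Node:
            m = Node(n.label, n.age, n.rate)
            mapping[n] = m
            for c in n.children:
                m.add_child(clone(c))
            return m

        return TimeTree(clone(self.root)), mapping

    # ------------------------------------------------------------------
    # Newick I/O (branch lengths in ka; ages recovered from depths)
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                core = _quote(n.label or "")
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.parent is None:
                return core
            return f"{core}:{n.duration:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str,
                    tip_ages: Optional[dict[str, float]] = None) -> "TimeTree":
        """Parse a Newick string with branch lengths in ka.

        Node ages are recovered from root-to-node depths.  Without
        ``tip_ages`` the deepest tip is taken to be extant (age 0); with
        ``tip_ages`` the stated ages pin the time scale (they must be
        mutually consistent with the branch lengths).
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        root = Node()
        depth: dict[Node, float] = {root: 0.0}

        def build(dnode, node):
            for dchild in dnode.child_nodes():
                lbl = dchild.taxon.label if dchild.taxon is not None else \
                    (dchild.label or None)
                child = node.add_child(Node(lbl))
                edge = dchild.edge.length if dchild.edge.length is not None else 0.0
                depth[child] = depth[node] + float(edge)
                build(dchild, child)

        build(dtree.seed_node, root)
        tree = cls(root)
        leaves = tree.tips()
        if tip_ages:
            heights = [depth[t] + tip_ages.get(t.label, 0.0) for t in leaves]
            height = heights[0]
            if max(heights) - min(heights) > 1e-6:
                raise ValueError("tip ages inconsistent with branch lengths")
        else:
            height = max(depth[t] for t in leaves)
        for node in tree.postorder():
            node.age = height - depth[node]
            if node.is_leaf and abs(node.age) < AGE_TOL:
                node.age = 0.0
        return tree

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.4g})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label
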