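"""Rooted-tree container for topology-only cladogram analyses.

The trees handled here are cladograms: rooted, with uniquely labelled tips,
arbitrary polytomies allowed, and branch lengths optional (accepted on input
and carried along, but no algorithm in this package uses them).  Newick
reading goes through :mod:`dendropy`; the in-memory representation is a
minimal node/parent structure that the parsimony and sister-group code can
walk without any external dependency.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

import dendropy

from .errors import NewickParseError, TreeStructureError

__all__ = ["Node", "Tree", "parse_newick", "write_newick"]


class Node:
    """A single node of a rooted tree.

    Tips carry a label and no children; internal nodes carry an ordered,
    non-empty child list (two or more children) and an optional label.
    """

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[Sequence["Node"]] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        for child in children or ():
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        # iterative to keep deep ladders safe from recursion limits
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> Iterator["Node"]:
        return (n for n in self.preorder() if n.is_tip)

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def tip_set(self) -> frozenset[str]:
        return frozenset(self.tip_labels())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_tip:
            return f"Node({self.label!r})"
        return f"Node({self.label!r}, {len(self.children)} children)"


class Tree:
    """A rooted phylogeny with uniquely labelled tips.

    Parameters
    ----------
    root:
        Root node of an already-linked node structure.
    outgroup:
        Optional tip label marking the outgroup used to root / polarise
        characters.  Purely informational; algorithms take explicit
        ancestral-state arguments.
    """

    def __init__(self, root: Node, outgroup: Optional[str] = None):
        self.root = root
        self.outgroup = outgroup
        self._validate()
        self._tip_index = {n.label: n for n in self.root.tips()}
        if outgroup is not None and outgroup not in self._tip_index:
            raise TreeStructureError(f"outgroup {outgroup!r} is not a tip of the tree")

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            if node.is_tip:
                if not node.label:
                    raise TreeStructureError("tip with empty label")
                if node.label in seen:
                    raise TreeStructureError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) < 2:
                raise TreeStructureError(
                    "internal node with a single child (empty tip label or "
                    "unresolved unary node in input)")
            for child in node.children:
                if child.parent is not node:
                    raise TreeStructureError("broken parent link")
        if self.root.parent is not None:
            raise TreeStructureError("root has a parent")

    # -- queries -----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    def tips(self) -> Iterator[Node]:
        return self.root.tips()

    def tip_labels(self) -> list[str]:
        return self.root.tip_labels()

    def tip(self, label: str) -> Node:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"no tip labelled {label!r}") from None

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        labels = list(labels)
        if not labels:
            raise ValueError("mrca of an empty tip set")
        paths = []
        for label in labels:
            node: Optional[Node] = self.tip(label)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        assert mrca is not None  # all paths start at the root
        return mrca

    def clusters(self) -> frozenset[frozenset[str]]:
        """Set of tip-sets of all internal nodes (topology fingerprint)."""
        return frozenset(n.tip_set() for n in self.preorder() if not n.is_tip)

    def write_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_tips} tips)"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_to_newick(node: Node) -> str:
    if node.is_tip:
        return _quote(node.label)
    inner = ",".join(_node_to_newick(c) for c in node.children)
    return f"({inner})" + (_quote(node.label) if node.label else "")


def write_newick(tree: Tree) -> str:
    """Serialise a tree as a single rooted Newick statement."""
    return _node_to_newick(tree.root) + ";"


def _convert(dnode: "dendropy.Node") -> Node:
    length = dnode.edge.length if dnode.edge is not None else None
    if not dnode.child_nodes():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(label=label, length=length)
    node = Node(label=dnode.label, length=length)
    for child in dnode.child_nodes():
        node.add_child(_convert(child))
    return node


def parse_newick(text: str, outgroup: Optional[str] = None) -> Tree:
    """Parse a single rooted Newick statement into a :class:`Tree`.

    Branch lengths are accepted and stored but ignored by every analysis
    (the data model is a cladogram).  Underscores in labels are preserved
    verbatim.  Malformed input (unbalanced parentheses, duplicate or empty
    tip labels) raises :class:`NewickParseError` naming the problem.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several reader subclasses
        raise NewickParseError(str(exc)) from exc
    root = _convert(dtree.seed_node)
    try:
        return Tree(root, outgroup=outgroup)
    except TreeStructureError as exc:
        raise NewickParseError(str(exc)) from exc
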