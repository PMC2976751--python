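"""Rooted phylogenetic trees: strict newick I/O, outgroup rooting,
Robinson-Foulds distance, and majority-rule(-extended) consensus.

Every tree in this package is *rooted*, and clades -- the sets of leaf
labels below internal nodes -- are the unit of topological comparison
throughout.  In particular :func:`rf_distance` is the rooted clade-set
Robinson-Foulds distance, which generally differs from the unrooted
(bipartition) RF distance computed by most phylogenetics software.

The newick dialect is deliberately strict: quoted labels and bracketed
comments are rejected with a position-reporting error rather than being
skipped, labels after a ``)`` are parsed and kept (they carry consensus
supports on output), and branch lengths must be non-negative numbers.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

__all__ = [
    "NewickError",
    "TreeError",
    "Node",
    "RootedTree",
    "SupportTree",
    "parse_newick",
    "write_newick",
    "root_by_outgroup",
    "rf_distance",
    "majority_consensus",
]

UNITS = ("none", "coalescent", "mutation", "generations")


class NewickError(ValueError):
    """Malformed newick input.  ``position`` is the 0-based offset."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


class Node:
    """A node of a rooted tree.  Leaves carry labels; any node may carry
    an edge length (the length of the edge to its parent)."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaf_nodes(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaf_nodes())

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        for child in self.children:
            new.add_child(child.copy())
        return new


class RootedTree:
    """A rooted, possibly multifurcating, leaf-labelled tree.

    Parameters
    ----------
    root:
        The root :class:`Node`.
    units:
        Tag recording what edge lengths mean: one of ``none``,
        ``coalescent``, ``mutation`` or ``generations``.
    """

    __slots__ = ("root", "units")

    def __init__(self, root: Node, units: str = "none"):
        if units not in UNITS:
            raise TreeError(f"unknown unit tag {units!r}; expected one of {UNITS}")
        self.root = root
        self.units = units

    # -- basic queries -------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaf_nodes())

    def clade_map(self) -> dict[int, frozenset[str]]:
        """Map ``id(node) -> leaf-label set below node`` for every node."""
        clades: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf():
                clades[id(node)] = frozenset((node.label,))
            else:
                acc: frozenset[str] = frozenset()
                for child in node.children:
                    acc = acc | clades[id(child)]
                clades[id(node)] = acc
        return clades

    def clades(self) -> frozenset[frozenset[str]]:
        """Clades of all internal nodes (including the root clade)."""
        cm = self.clade_map()
        return frozenset(cm[id(n)] for n in self.root.postorder() if not n.is_leaf())

    def nontrivial_clades(self) -> frozenset[frozenset[str]]:
        """Internal clades excluding the full leaf set (and singletons)."""
        full = self.leaf_labels
        return frozenset(c for c in self.clades() if 1 < len(c) < len(full))

    def internal_edge_clades(self) -> list[frozenset[str]]:
        """Clades identifying internal *edges*: one per non-root internal
        node (the edge above it), in deterministic order."""
        cm = self.clade_map()
        out = [
            cm[id(n)]
            for n in self.root.postorder()
            if not n.is_leaf() and n.parent is not None
        ]
        return sorted(out, key=lambda c: (len(c), tuple(sorted(c))))

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.postorder() if not n.is_leaf()
        )

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy(), self.units)

    # -- output --------------------------------------------------------

    def newick(
        self,
        lengths: bool = True,
        internal_labels: bool = True,
        label_fn: Callable[[frozenset[str]], str | None] | None = None,
    ) -> str:
        """Canonical newick string: children ordered by their smallest
        descendant label, so equal topologies print identically."""
        cm = self.clade_map()

        def fmt_len(x: float) -> str:
            return format(x, ".12g")

        def write(node: Node) -> str:
            if node.is_leaf():
                s = node.label
            else:
                # order children by smallest descendant label
                kids = sorted(node.children, key=lambda c: min(cm[id(c)]))
                s = "(" + ",".join(write(c) for c in kids) + ")"
                if label_fn is not None:
                    lab = label_fn(cm[id(node)])
                    if lab is not None:
                        s += lab
                elif internal_labels and node.label:
                    s += node.label
            if lengths and node.length is not None:
                s += ":" + fmt_len(node.length)
            return s

        return write(self.root) + ";"

    def topology_newick(self) -> str:
        """Canonical topology-only newick (no lengths, no labels on
        internal nodes); equal iff the clade sets are equal."""
        return self.newick(lengths=False, internal_labels=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({self.newick()!r}, units={self.units!r})"


@dataclass
class SupportTree:
    """A rooted tree annotated with per-internal-clade support proportions
    in [0, 1] (e.g. clade frequencies from a consensus or bootstrap)."""

    tree: RootedTree
    supports: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for clade, s in self.supports.items():
            if not 0.0 <= s <= 1.0:
                raise TreeError(f"support {s} for clade {sorted(clade)} not in [0, 1]")

    def newick(self, precision: int = 3) -> str:
        def label(clade: frozenset) -> str | None:
            s = self.supports.get(clade)
            return None if s is None else format(s, f".{precision}g")

        return self.tree.newick(lengths=False, label_fn=label)


# ---------------------------------------------------------------------
# newick parsing
# ---------------------------------------------------------------------

_LABEL_RE = re.compile(r"[A-Za-z0-9_.+#|\-]+")
_NUM_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


class _Cursor:
    __slots__ = ("text", "pos")

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""


def _check_unsupported(c: _Cursor) -> None:
    ch = c.peek()
    if ch in "'\"":
        raise NewickError("quoted labels are not supported", c.pos)
    if ch == "[":
        raise NewickError("bracketed comments are not supported", c.pos)


def _read_label(c: _Cursor) -> str | None:
    _check_unsupported(c)
    m = _LABEL_RE.match(c.text, c.pos)
    if m is None:
        return None
    c.pos = m.end()
    return m.group(0)


def _read_length(c: _Cursor) -> float | None:
    c.skip_ws()
    if c.peek() != ":":
        return None
    c.pos += 1
    c.skip_ws()
    m = _NUM_RE.match(c.text, c.pos)
    if m is None:
        raise NewickError("expected a branch length after ':'", c.pos)
    c.pos = m.end()
    value = float(m.group(0))
    if value < 0:
        raise NewickError(f"negative branch length {value}", m.start())
    return value


def _parse_node(c: _Cursor) -> Node:
    c.skip_ws()
    _check_unsupported(c)
    if c.peek() == "(":
        start = c.pos
        c.pos += 1
        node = Node()
        node.add_child(_parse_node(c))
        c.skip_ws()
        while c.peek() == ",":
            c.pos += 1
            node.add_child(_parse_node(c))
            c.skip_ws()
        if c.peek() != ")":
            raise NewickError("expected ',' or ')'", c.pos if c.peek() else start)
        c.pos += 1
        _check_unsupported(c)
        node.label = _read_label(c)  # optional internal label (e.g. support)
    else:
        start = c.pos
        label = _read_label(c)
        if label is None:
            raise NewickError("expected a leaf label", start)
        node = Node(label=label)
    node.length = _read_length(c)
    return node


def parse_newick(text: str, units: str = "none") -> RootedTree:
    """Parse a single ';'-terminated newick statement into a RootedTree.

    Raises :class:`NewickError` (with the offending position) on
    unbalanced parentheses, missing/duplicate/empty leaf labels, quoted
    labels, bracketed comments, or trailing garbage.
    """
    c = _Cursor(text)
    c.skip_ws()
    root = _parse_node(c)
    c.skip_ws()
    if c.peek() != ";":
        raise NewickError("expected ';' at end of tree", c.pos)
    c.pos += 1
    c.skip_ws()
    if c.pos != len(c.text):
        raise NewickError("trailing characters after ';'", c.pos)
    labels = [n.label for n in root.leaf_nodes()]
    dupes = [lab for lab, k in Counter(labels).items() if k > 1]
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
    return RootedTree(root, units=units)


def write_newick(tree: RootedTree, lengths: bool = True) -> str:
    return tree.newick(lengths=lengths)


# ---------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------


def root_by_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    """Re-root so that ``outgroup`` is one of the two children of the root.

    The ingroup clade structure induced from the unrooted version of the
    input is preserved.  A single leaf must carry the outgroup label.
    """
    t = tree.copy()
    matches = [n for n in t.root.leaf_nodes() if n.label == outgroup]
    if not matches:
        raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")
    if len(matches) > 1:
        raise TreeError(
            f"multiple leaves are labelled {outgroup!r}; "
            "multiple species cannot simultaneously be designated as outgroups"
        )
    leaf = matches[0]
    parent = leaf.parent
    if parent is None:
        raise TreeError("cannot root a single-leaf tree")

    if parent is t.root and len(t.root.children) == 2:
        return RootedTree(t.root, units=t.units)

    parent.remove_child(leaf)

    # reverse parent pointers along the path parent -> old root
    path: list[Node] = []
    n: Node | None = parent
    while n is not None:
        path.append(n)
        n = n.parent
    edge_lengths = [n.length for n in path]
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
        path[i].parent = None
    for i in range(len(path) - 1):
        path[i].add_child(path[i + 1])
        path[i + 1].length = edge_lengths[i]
    path[0].length = None

    # suppress the old root if it became a unifurcation
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        child = old_root.children[0]
        grand = old_root.parent
        if child.length is not None and old_root.length is not None:
            child.length = child.length + old_root.length
        elif child.length is None:
            child.length = old_root.length
        grand.children.remove(old_root)
        grand.add_child(child)

    new_root = Node()
    new_root.add_child(leaf)
    new_root.add_child(parent)
    return RootedTree(new_root, units=t.units)


# ---------------------------------------------------------------------
# Robinson-Foulds distance (rooted clade convention)
# ---------------------------------------------------------------------


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Size of the symmetric difference of the two non-trivial clade sets.

    This is the rooted-tree RF convention: clades, not bipartitions.
    Zero iff the topologies (clade sets) are identical.
    """
    if t1.leaf_labels != t2.leaf_labels:
        raise TreeError(
            "trees have different leaf sets: "
            f"{sorted(t1.leaf_labels ^ t2.leaf_labels)} not shared"
        )
    return len(t1.nontrivial_clades() ^ t2.nontrivial_clades())


# ---------------------------------------------------------------------
# majority-rule(-extended) consensus
# ---------------------------------------------------------------------


def _compatible(c1: frozenset, c2: frozenset) -> bool:
    return c1.isdisjoint(c2) or c1 <= c2 or c2 <= c1


def _tree_from_clades(
    leafset: frozenset[str], clades: Sequence[frozenset]
) -> RootedTree:
    ordered = sorted(set(clades), key=lambda c: (-len(c), tuple(sorted(c))))
    root = Node()
    nodes: list[tuple[frozenset, Node]] = [(leafset, root)]
    for clade in ordered:
        if clade == leafset:
            continue
        node = Node()
        # attach to the smallest already-placed clade strictly containing it
        host = min(((c, n) for c, n in nodes if clade < c), key=lambda cn: len(cn[0]))
        host[1].add_child(node)
        nodes.append((clade, node))
    for leaf in sorted(leafset):
        host = min(
            ((c, n) for c, n in nodes if leaf in c), key=lambda cn: len(cn[0])
        )
        host[1].add_child(Node(label=leaf))
    return RootedTree(root)


def majority_consensus(
    trees: Sequence[RootedTree], threshold: float = 0.5, extended: bool = True
) -> SupportTree:
    """Majority-rule consensus of rooted trees over a common leaf set.

    Clades occurring in a proportion strictly greater than ``threshold``
    of the input trees are included, annotated with their frequency.
    With ``extended=True`` (majority-rule extended, MRe), the remaining
    clades are then greedily added in order of decreasing frequency when
    compatible with everything already accepted; ties are broken by the
    lexicographically smallest sorted leaf tuple, which makes the result
    deterministic.
    """
    if not trees:
        raise TreeError("consensus of an empty tree collection")
    if not 0.5 <= threshold <= 1.0:
        raise TreeError(f"threshold {threshold} outside [0.5, 1]")
    leafset = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leafset:
            raise TreeError("consensus requires a common leaf set")

    counts: Counter = Counter()
    for t in trees:
        counts.update(t.nontrivial_clades())
    n = len(trees)
    freqs = {clade: k / n for clade, k in counts.items()}

    accepted = [c for c, f in freqs.items() if f > threshold]
    if extended:
        rest = sorted(
            (c for c, f in freqs.items() if f <= threshold),
            key=lambda c: (-freqs[c], tuple(sorted(c))),
        )
        for c in rest:
            if all(_compatible(c, a) for a in accepted):
                accepted.append(c)

    tree = _tree_from_clades(leafset, accepted)
    supports = {c: freqs[c] for c in accepted}
    supports[leafset] = 1.0
    return SupportTree(tree, supports)
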