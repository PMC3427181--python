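"""A lightweight phylogenetic tree with Newick I/O.

The class carries exactly what the downstream algorithms need: a rooted
node structure (a degree-3 "root" represents an unrooted tree, the usual
Newick convention), nonnegative branch lengths, optional bootstrap supports
on internal edges, leaf-set bookkeeping and midpoint rooting.  Newick
parsing is delegated to dendropy; serialization is done directly so the
written form is fully under our control.

Edges are identified throughout the package by the frozenset of leaf labels
of the child clade (under the rooting in force).
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

from .errors import (
    DuplicateIdError,
    NewickParseError,
    ReferenceIdError,
    TreeShapeError,
)


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length}>"


class PhyloTree:
    """Leaf-labeled tree with branch lengths and optional supports."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "Duplicate" in type(exc).__name__ or "same taxa" in str(exc):
                raise DuplicateIdError(f"duplicate leaf label: {exc}") from exc
            raise NewickParseError(f"cannot parse Newick: {exc}") from exc

        def convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            support = None
            if dn.child_nodes() and label is not None:
                # internal numeric labels in [0, 100] are bootstrap supports
                try:
                    val = float(label)
                except ValueError:
                    val = None
                if val is not None and 0.0 <= val <= 100.0:
                    support, label = val, None
            node = Node(label=label, length=dn.edge.length, support=support)
            for dc in dn.child_nodes():
                node.add_child(convert(dc))
            return node

        root = convert(dt.seed_node)
        root.length = None  # no edge above the root
        return cls(root)

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise DuplicateIdError(f"duplicate leaf label {lab!r}")
                seen.add(lab)
        if any(lab is None for lab in labels):
            raise NewickParseError("unlabeled leaf")
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeShapeError(f"negative branch length {node.length}")
            if node.support is not None and not (0 <= node.support <= 100):
                raise TreeShapeError(f"support {node.support} outside [0, 100]")

    # -- traversal --------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[Node]:
        """All edges, each represented by its child node (root excluded)."""
        return [n for n in self.postorder() if n is not self.root]

    def leafset_map(self) -> dict[int, frozenset]:
        """id(node) -> frozenset of leaf labels below (incl. the node)."""
        out: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.label])
            else:
                s: frozenset = frozenset()
                for c in node.children:
                    s |= out[id(c)]
                out[id(node)] = s
        return out

    def edge_ids(self) -> list[frozenset]:
        """Child-clade leafsets of all edges, postorder."""
        ls = self.leafset_map()
        return [ls[id(n)] for n in self.edges()]

    def node_by_edge(self) -> dict[frozenset, Node]:
        ls = self.leafset_map()
        return {ls[id(n)]: n for n in self.edges()}

    def find_node(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise ReferenceIdError(f"no node labeled {label!r}")

    def mrca(self, labels) -> Node:
        want = frozenset(labels)
        missing = want - set(self.leaf_labels())
        if missing:
            raise ReferenceIdError(f"labels not in tree: {sorted(missing)}")
        ls = self.leafset_map()
        best: Optional[Node] = None
        for node in self.postorder():
            if want <= ls[id(node)]:
                if best is None or len(ls[id(node)]) < len(ls[id(best)]):
                    best = node
        assert best is not None
        return best

    # -- shape ------------------------------------------------------------

    @property
    def is_rooted(self) -> bool:
        """Degree-2 root == explicitly rooted tree."""
        return len(self.root.children) == 2

    def is_binary_unrooted(self) -> bool:
        if len(self.root.children) != 3:
            return False
        return all(
            len(n.children) in (0, 2) for n in self.postorder() if n is not self.root
        )

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions of the leaf set, rooting-independent.

        Each bipartition is a frozenset of the two side-leafsets.
        """
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset] = set()
        ls = self.leafset_map()
        for node in self.edges():
            side = ls[id(node)]
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset([side, other]))
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    # -- copying / rerooting ----------------------------------------------

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            n = Node(node.label, node.length, node.support)
            for c in node.children:
                n.add_child(dup(c))
            return n

        return PhyloTree(dup(self.root))

    def midpoint_rooted(self) -> "PhyloTree":
        """Return a copy rooted at the midpoint of the longest leaf-leaf path."""
        t = self.copy()
        leaves = t.leaves()
        if len(leaves) < 2:
            raise TreeShapeError("midpoint rooting needs >= 2 leaves")

        # undirected adjacency with edge lengths
        adj: dict[int, list[tuple[Node, float]]] = {}
        nodes = list(t.postorder())
        for n in nodes:
            adj.setdefault(id(n), [])
        for n in nodes:
            if n.parent is not None:
                w = n.length or 0.0
                adj[id(n)].append((n.parent, w))
                adj[id(n.parent)].append((n, w))
        by_id = {id(n): n for n in nodes}

        def farthest(src: Node):
            dist = {id(src): 0.0}
            prev: dict[int, Node] = {}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[id(u)]:
                    if id(v) not in dist:
                        dist[id(v)] = dist[id(u)] + w
                        prev[id(v)] = u
                        stack.append(v)
            best = max(
                (n for n in nodes if n.is_leaf),
                key=lambda n: (dist[id(n)], n.label),
            )
            return best, dist, prev

        u, _, _ = farthest(leaves[0])
        v, dist, prev = farthest(u)
        diameter = dist[id(v)]
        # path from v back to u
        path = [v]
        while id(path[-1]) in prev:
            path.append(prev[id(path[-1])])
        # walk from u toward v until the midpoint
        path = path[::-1]  # u .. v ? no: path currently v..u reversed -> u? fix below
        if path[0] is not u:
            path = path[::-1]
        half = diameter / 2.0

        def edge_len(a: Node, b: Node) -> float:
            child = a if a.parent is b else b
            return child.length or 0.0

        acc = 0.0
        for a, b in zip(path, path[1:]):
            w = edge_len(a, b)
            if acc + w >= half - 1e-12:
                offset = half - acc  # distance from a along edge (a, b)
                return t._reroot_on_edge(a, b, offset)
            acc += w
        # numerical fallback: root at the far node
        return t._reroot_at_node(path[-1])

    def _reroot_on_edge(self, a: Node, b: Node, offset: float) -> "PhyloTree":
        """Root on edge (a, b), `offset` from a (edge direction a->b)."""
        child = a if a.parent is b else b
        parent = b if child is a else a
        w = child.length or 0.0
        d_child = offset if child is a else w - offset
        d_child = min(max(d_child, 0.0), w)
        if d_child <= 1e-12 and not child.is_leaf:
            return self._reroot_at_node(child)
        if w - d_child <= 1e-12:
            return self._reroot_at_node(parent)
        new_root = Node()
        self._invert(parent)
        parent.length = w - d_child
        child.length = d_child
        if child in parent.children:
            parent.children.remove(child)
        child.parent = None
        new_root.add_child(child)
        new_root.add_child(parent)
        _suppress_unifurcations(new_root)
        return PhyloTree(new_root)

    def _reroot_at_node(self, node: Node) -> "PhyloTree":
        if node.parent is None:
            return PhyloTree(node)
        self._invert(node)
        node.parent = None
        node.length = None
        _suppress_unifurcations(node)
        return PhyloTree(node)

    def _invert(self, node: Node) -> None:
        """Reverse all parent links on the path from `node` up to the root."""
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        # path: node .. old_root; make each upper node a child of the lower
        for lower, upper in zip(path, path[1:]):
            upper.children.remove(lower)
        for lower, upper in zip(path, path[1:]):
            upper.parent = lower
            lower.children.append(upper)
            upper.length = lower.length
            upper.support = lower.support

    # -- serialization ----------------------------------------------------

    def to_newick(self, include_supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.label)
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = ""
                if include_supports and node.support is not None:
                    lab = _fmt_num(node.support)
                elif node.label:
                    lab = _quote(node.label)
                s = f"({inner}){lab}"
            if node.length is not None and node.parent is not None:
                s += f":{_fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"

    def write_newick(self, path, include_supports: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_supports=include_supports) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_leaves} leaves>"


def _suppress_unifurcations(root: Node) -> None:
    """Collapse internal nodes with a single child (merging branch lengths).

    Rerooting can leave the old root as a unary pass-through node.
    """
    stack = [root]
    while stack:
        node = stack.pop()
        while len(node.children) == 1 and node.parent is not None:
            only = node.children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = only
            only.parent = parent
            node = only
        if node.parent is None and len(node.children) == 1 and not node.children[0].is_leaf:
            # unary root: promote the grandchildren (edge above has no meaning)
            only = node.children[0]
            node.children = only.children
            node.label = node.label or only.label
            for c in node.children:
                c.parent = node
        stack.extend(node.children)


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".10g")


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    """Unrooted topology equality via bipartition sets."""
    if set(a.leaf_labels()) != set(b.leaf_labels()):
        return False
    return a.bipartitions() == b.bipartitions()
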