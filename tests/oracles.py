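"""Independent reference implementations used only as test oracles.

Deliberately written with different algorithms/data structures than the
package: set-based Fitch, explicit enumeration of internal states and of
tree topologies, codon-pair scanning + scipy shortest paths, and normal
equation OLS over explicitly traced leaf paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import shortest_path

from modevoprof.tree import Node, PhyloTree

MISSING = set("-X")


def fitch_count(tree: PhyloTree, column: dict[str, str], alphabet: str) -> int:
    """Set-intersection Fitch parsimony (binary trees; missing = full set)."""
    full = frozenset(alphabet)

    def post(node):
        if node.is_leaf:
            ch = column[node.label]
            return (full, 0) if ch in MISSING else (frozenset(ch), 0)
        (s1, c1), (s2, c2) = (post(ch) for ch in node.children)
        inter = s1 & s2
        if inter:
            return inter, c1 + c2
        return s1 | s2, c1 + c2 + 1

    root = tree.root
    if len(root.children) == 3:
        # treat the unrooted trifurcation as a rooted cherry for counting
        a, b, c = root.children
        tmp = Node()
        inner = Node()
        for ch in (a, b):
            inner.children.append(ch)
        tmp.children = [inner, c]
        count = _fitch_on(tmp, column, full)
        return count
    return post(root)[1]


def _fitch_on(root, column, full):
    def post(node):
        if not node.children:
            ch = column[node.label]
            return (full, 0) if ch in MISSING else (frozenset(ch), 0)
        sets_costs = [post(c) for c in node.children]
        s1, c1 = sets_costs[0]
        total = c1
        cur = s1
        for s2, c2 in sets_costs[1:]:
            total += c2
            inter = cur & s2
            if inter:
                cur = inter
            else:
                cur = cur | s2
                total += 1
        return cur, total

    return post(root)[1]


def exhaustive_min_changes(tree: PhyloTree, column: dict[str, str]) -> int:
    """Minimum unit-cost changes by enumerating internal-node states.

    Internal states are restricted to the residues observed in the column,
    which is sufficient for the unit-cost optimum.
    """
    observed = sorted({c for c in column.values() if c not in MISSING})
    if not observed:
        return 0
    internals = [n for n in tree.postorder() if not n.is_leaf]
    edges = [(n.parent, n) for n in tree.postorder() if n.parent is not None]
    best = np.inf
    for assign in itertools.product(observed, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        cost = 0
        for parent, child in edges:
            ps = state[id(parent)]
            if child.is_leaf:
                ch = column[child.label]
                if ch in MISSING:
                    continue
                cost += ch != ps
            else:
                cost += state[id(child)] != ps
            if cost >= best:
                break
        best = min(best, cost)
    return int(best)


def all_unrooted_topologies(labels) -> list[PhyloTree]:
    """Every unrooted binary topology on the labels, by edge insertion."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def base():
        root = Node()
        for lab in labels[:3]:
            root.add_child(Node(label=lab, length=1.0))
        return root

    trees = [base()]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            edges = [n for n in _postorder(t) if n.parent is not None]
            for k in range(len(edges)):
                t2 = _copy(t)
                edges2 = [n for n in _postorder(t2) if n.parent is not None]
                target = edges2[k]
                parent = target.parent
                mid = Node(length=1.0)
                idx = parent.children.index(target)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(label=lab, length=1.0))
                nxt.append(t2)
        trees = nxt
    return [PhyloTree(t) for t in trees]


def _postorder(root):
    out = []

    def rec(n):
        for c in n.children:
            rec(c)
        out.append(n)

    rec(root)
    return out


def _copy(root):
    n = Node(root.label, root.length)
    for c in root.children:
        n.add_child(_copy(c))
    return n


def additive_distances(tree: PhyloTree):
    """Path-length distance matrix (labels sorted) from a tree."""
    labels = sorted(tree.leaf_labels())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    ls = tree.leafset_map()
    for child in tree.edges():
        side = {idx[lab] for lab in ls[id(child)]}
        w = child.length or 0.0
        for i, j in itertools.combinations(range(n), 2):
            if (i in side) != (j in side):
                d[i, j] += w
                d[j, i] += w
    return labels, d


def brute_force_code_costs(amino_acids: str) -> np.ndarray:
    """Genetic-code step costs built independently: scan all sense-codon
    pairs for single-nucleotide differences, then scipy shortest paths."""
    from Bio.Data import CodonTable

    fwd = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    codons = sorted(fwd)
    n = len(amino_acids)
    idx = {a: i for i, a in enumerate(amino_acids)}
    adj = np.zeros((n, n))
    for c1, c2 in itertools.combinations(codons, 2):
        diffs = sum(x != y for x, y in zip(c1, c2))
        if diffs == 1 and fwd[c1] != fwd[c2]:
            a, b = idx[fwd[c1]], idx[fwd[c2]]
            adj[a, b] = adj[b, a] = 1
    dist = shortest_path(adj, method="FW", unweighted=True)
    return dist.astype(int)


def ols_total_length(tree: PhyloTree, labels, d) -> float:
    """OLS tree length via normal equations over explicitly traced paths."""
    idx = {lab: i for i, lab in enumerate(labels)}
    leaves = {n.label: n for n in tree.leaves()}
    edges = tree.edges()
    eidx = {id(n): k for k, n in enumerate(edges)}

    def path_edges(a, b):
        anc_a = []
        cur = leaves[a]
        while cur is not None:
            anc_a.append(cur)
            cur = cur.parent
        seen = {id(x) for x in anc_a}
        path = []
        cur = leaves[b]
        while id(cur) not in seen:
            path.append(cur)
            cur = cur.parent
        meet = cur
        for x in anc_a:
            if x is meet:
                break
            path.append(x)
        return [eidx[id(x)] for x in path]

    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for e in path_edges(a, b):
            A[r, e] = 1.0
        y[r] = d[idx[a], idx[b]]
    x = np.linalg.pinv(A.T @ A) @ (A.T @ y)
    return float(x.sum())
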