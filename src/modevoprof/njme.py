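"""Neighbor joining, OLS minimum-evolution NNI refinement, and bootstrap.

``nj_tree`` is the standard Saitou–Nei agglomeration (Studier–Keppler Q
matrix).  Negative estimated branch lengths are clamped to zero with the
deficit transferred to the sibling branch so the pair's total is preserved.
``me_nni_refine`` hill-climbs over nearest-neighbor interchanges, accepting
at each step the interchange that most reduces the ordinary-least-squares
total branch length; scan order is deterministic (edges in canonical order
of their sorted child leafsets).  ``bootstrap_support`` resamples alignment
columns with replacement and reports, per internal edge of the point
estimate, the percentage of replicates containing the same bipartition.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np

from .alignment import ProteinAlignment
from .distances import DistanceMatrix, pairwise_distances
from .errors import BootstrapFailureError, SaturationError, TreeShapeError
from .tree import Node, PhyloTree


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (unrooted; degree-3 root for n >= 3)."""
    n = D.n
    if n < 3:
        raise TreeShapeError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(label=i) for i in D.ids]
    d = D.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)  # first minimum: deterministic
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        gi, gj = active[i_loc], active[j_loc]
        dij = d[gi, gj]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = Node()
        ci, cj = nodes[gi], nodes[gj]
        ci.length, cj.length = li, lj
        parent.add_child(ci)
        parent.add_child(cj)
        # distances to the new node
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    # join the last three around a degree-3 root
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = Node()
    for g, length in ((a, la), (b, lb), (c, lc)):
        nodes[g].length = max(length, 0.0)
        root.add_child(nodes[g])
    return PhyloTree(root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative estimate to 0, moving the deficit to the sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# OLS branch lengths / minimum evolution


def ols_branch_lengths(tree: PhyloTree, D: DistanceMatrix) -> tuple[np.ndarray, float]:
    """OLS edge-length estimates and the resulting total tree length."""
    labels = list(D.ids)
    index = {lab: k for k, lab in enumerate(labels)}
    edges = tree.edges()
    ls = tree.leafset_map()
    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    for e_idx, child in enumerate(edges):
        side = {index[lab] for lab in ls[id(child)]}
        for p_idx, (i, j) in enumerate(pairs):
            if (i in side) != (j in side):
                A[p_idx, e_idx] = 1.0
    dvec = np.array([D.d[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, dvec, rcond=None)
    return x, float(x.sum())


def me_nni_refine(tree: PhyloTree, D: DistanceMatrix) -> PhyloTree:
    """Greedy NNI hill-climb minimizing OLS total branch length.

    Requires a binary unrooted tree over exactly D's taxa.  The returned
    tree carries the final OLS branch lengths (clamped at zero).
    """
    if set(tree.leaf_labels()) != set(D.ids):
        raise TreeShapeError("tree and distance matrix taxa differ")
    if not tree.is_binary_unrooted():
        raise TreeShapeError("NNI refinement requires a binary unrooted tree")
    current = tree.copy()
    _, cur_len = ols_branch_lengths(current, D)

    while True:
        best: Optional[tuple[float, tuple]] = None
        for p, c, x, z in _nni_moves(current):
            _swap(p, c, x, z)
            _, length = ols_branch_lengths(current, D)
            _swap(p, c, z, x)  # revert
            if length < cur_len - 1e-12 and (best is None or length < best[0]):
                best = (length, (p, c, x, z))
        if best is None:
            break
        cur_len, (p, c, x, z) = best
        _swap(p, c, x, z)

    lengths, _ = ols_branch_lengths(current, D)
    for child, est in zip(current.edges(), lengths):
        child.length = max(float(est), 0.0)
    return current


def _nni_moves(tree: PhyloTree):
    """Candidate swaps in deterministic canonical order.

    Yields (p, c, x, z): move child x of c to p and child z of p to c.
    Both NNIs of every internal edge are covered (possibly with duplicates
    when p is the degree-3 root).
    """
    ls = tree.leafset_map()
    internal_edges = [
        n
        for n in tree.edges()
        if not n.is_leaf
    ]
    internal_edges.sort(key=lambda n: tuple(sorted(ls[id(n)])))
    for c in internal_edges:
        p = c.parent
        for z in [ch for ch in p.children if ch is not c]:
            for x in list(c.children):
                yield p, c, x, z


def _swap(p: Node, c: Node, x: Node, z: Node) -> None:
    """Exchange subtree x (child of c) with subtree z (child of p)."""
    c.children[c.children.index(x)] = z
    p.children[p.children.index(z)] = x
    x.parent, z.parent = p, c


# ---------------------------------------------------------------------------
# bootstrap


def build_tree(
    aln: ProteinAlignment,
    model: str = "gamma",
    alpha: float = 1.0,
    refine: bool = True,
) -> PhyloTree:
    """Distance tree from an alignment: NJ, optionally ME-refined."""
    D = pairwise_distances(aln, model=model, alpha=alpha)
    t = nj_tree(D)
    if refine and t.is_binary_unrooted():
        t = me_nni_refine(t, D)
    return t


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int,
    seed: int,
    model: str = "gamma",
    alpha: float = 1.0,
    refine: bool = False,
    point_tree: Optional[PhyloTree] = None,
    max_skip_fraction: float = 0.10,
) -> PhyloTree:
    """Nonparametric bootstrap supports on the point-estimate tree.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is rebuilt with the same distance model and NJ (plus NNI refinement if
    requested).  Support of an internal edge is the percentage of usable
    replicates containing the same bipartition.  Replicates with a
    saturated pair are skipped; more than ``max_skip_fraction`` skipped is
    an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if point_tree is None:
        point_tree = build_tree(aln, model=model, alpha=alpha, refine=refine)
    result = point_tree.copy()
    target = {bp: 0 for bp in result.bipartitions()}

    used = 0
    skipped = 0
    C = aln.n_cols
    for _ in range(n_reps):
        cols = rng.integers(1, C + 1, size=C)
        rep = aln.take_columns(cols.tolist())
        try:
            t = build_tree(rep, model=model, alpha=alpha, refine=refine)
        except SaturationError:
            skipped += 1
            continue
        used += 1
        for bp in t.bipartitions():
            if bp in target:
                target[bp] += 1
    if skipped > max_skip_fraction * n_reps:
        raise BootstrapFailureError(
            f"{skipped}/{n_reps} bootstrap replicates skipped (saturation)"
        )
    if used == 0:
        raise BootstrapFailureError("no usable bootstrap replicates")

    all_leaves = frozenset(result.leaf_labels())
    ls = result.leafset_map()
    for node in result.edges():
        side = ls[id(node)]
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2 and not node.is_leaf:
            bp = frozenset([side, other])
            node.support = 100.0 * target[bp] / used
    return result
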