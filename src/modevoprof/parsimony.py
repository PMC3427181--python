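"""Per-site parsimony substitution counting on a fixed ("user") tree.

The count engine is Sankoff dynamic programming with an arbitrary symmetric
step-cost matrix: at a leaf the cost is 0 for the observed residue and
infinite elsewhere; ``-`` and ``X`` are missing data (cost 0 everywhere);
an internal node's cost for state *s* is the sum over children of
``min_t cost(s, t) + child_cost(t)``; the per-column substitution count is
the minimum root-state cost.  With a symmetric cost matrix the count does
not depend on root placement.

A single most-parsimonious reconstruction (MPR) is obtained top-down with a
deterministic lexicographic tie-break (alphabetically first one-letter
code), and each branch is charged the step cost between the parent and
child states — under genetic-code costs that cost *is* the shortest-path
edge count, so per-column branch sums always equal the DP minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AA_INDEX, AMINO_ACIDS, GAP, UNKNOWN, ProteinAlignment
from .codecosts import CostMatrix
from .errors import ReferenceIdError, TreeShapeError
from .tree import Node, PhyloTree

_INF = np.inf


def _leaf_cost(aln_row: str) -> np.ndarray:
    """(20, n_cols) leaf cost array; missing symbols cost 0 in every state."""
    C = len(aln_row)
    cost = np.full((len(AMINO_ACIDS), C), _INF)
    for c, ch in enumerate(aln_row):
        if ch == GAP or ch == UNKNOWN:
            cost[:, c] = 0.0
        else:
            cost[AA_INDEX[ch], c] = 0.0
    return cost


def _check_labels(aln: ProteinAlignment, tree: PhyloTree) -> None:
    tree_labels = set(tree.leaf_labels())
    aln_labels = set(aln.ids)
    if tree_labels != aln_labels:
        only_t = sorted(tree_labels - aln_labels)
        only_a = sorted(aln_labels - tree_labels)
        raise ReferenceIdError(
            f"tree/alignment label mismatch: only in tree {only_t}, "
            f"only in alignment {only_a}"
        )


def _node_costs(
    aln: ProteinAlignment, tree: PhyloTree, cost: CostMatrix
) -> dict[int, np.ndarray]:
    """Sankoff bottom-up pass: id(node) -> (20, n_cols) cost array."""
    C = np.asarray(cost.cost, dtype=float)
    out: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[id(node)] = _leaf_cost(aln.row(node.label))
        else:
            total = None
            for child in node.children:
                child_cost = out[id(child)]
                # min over child states t of C[s, t] + child_cost[t, col]
                contrib = (C[:, :, None] + child_cost[None, :, :]).min(axis=1)
                total = contrib if total is None else total + contrib
            out[id(node)] = total
    return out


def sankoff_site_counts(
    aln: ProteinAlignment, tree: PhyloTree, cost: CostMatrix
) -> np.ndarray:
    """Minimal substitution count (or cost) per alignment column.

    Returns an integer array of length ``n_cols``.  Constant and all-missing
    columns score 0.
    """
    if tree.n_leaves < 2:
        raise TreeShapeError("parsimony needs at least 2 leaves")
    _check_labels(aln, tree)
    costs = _node_costs(aln, tree, cost)
    root_cost = costs[id(tree.root)]
    counts = root_cost.min(axis=0)
    return np.rint(counts).astype(int)


@dataclass(frozen=True)
class BranchCounts:
    """Per-(branch, column) event counts from one MPR.

    Branches are identified by the child-clade leafset under the rooting
    used (``rooting`` records whether the user tree was already rooted or
    was midpoint-rooted here).
    """

    edges: tuple[frozenset, ...]
    events: np.ndarray  # (n_edges, n_cols) int
    tie_break_tag: str
    rooting: str

    @property
    def n_cols(self) -> int:
        return self.events.shape[1]

    def column_sums(self) -> np.ndarray:
        return self.events.sum(axis=0)

    def rows_for(self, edge_ids) -> np.ndarray:
        index = {e: i for i, e in enumerate(self.edges)}
        missing = [e for e in edge_ids if e not in index]
        if missing:
            raise ReferenceIdError(f"edges not in tree: {missing[:3]}")
        return np.array([index[e] for e in edge_ids], dtype=int)


def reconstruct_branch_events(
    aln: ProteinAlignment,
    tree: PhyloTree,
    cost: CostMatrix,
    tie_break: str = "lexicographic",
) -> BranchCounts:
    """Assign per-branch substitution events from one deterministic MPR.

    Unrooted user trees are midpoint-rooted first (recorded in the result).
    At the root the minimum-cost state is chosen (ties: alphabetically first
    code); descending, each child takes the state minimizing transition cost
    plus its own subtree cost, same tie rule.
    """
    if tie_break != "lexicographic":
        raise ValueError(f"unknown tie break {tie_break!r}")
    if tree.n_leaves < 2:
        raise TreeShapeError("parsimony needs at least 2 leaves")
    _check_labels(aln, tree)
    if tree.is_rooted:
        rooted, rooting = tree, "user"
    else:
        rooted, rooting = tree.midpoint_rooted(), "midpoint"

    C = np.asarray(cost.cost, dtype=float)
    costs = _node_costs(aln, rooted, cost)
    ncols = aln.n_cols

    # top-down state assignment (argmin is the lexicographically first
    # minimizer because states are in alphabetical order)
    states: dict[int, np.ndarray] = {}
    states[id(rooted.root)] = np.argmin(costs[id(rooted.root)], axis=0)

    edges: list[frozenset] = []
    events_rows: list[np.ndarray] = []
    ls = rooted.leafset_map()
    for node in rooted.preorder():
        if node is rooted.root:
            continue
        parent_states = states[id(node.parent)]
        child_cost = costs[id(node)]
        # (20, ncols): transition cost from the fixed parent state + subtree
        scores = C[parent_states, :].T + child_cost
        child_states = np.argmin(scores, axis=0)
        states[id(node)] = child_states
        edges.append(ls[id(node)])
        events_rows.append(C[parent_states, child_states])

    events = np.rint(np.vstack(events_rows)).astype(int) if events_rows else np.zeros(
        (0, ncols), dtype=int
    )
    return BranchCounts(
        edges=tuple(edges),
        events=events,
        tie_break_tag="lexicographic",
        rooting=rooting,
    )
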