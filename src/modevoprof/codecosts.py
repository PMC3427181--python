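"""Amino-acid step costs consistent with the genetic code.

Protein parsimony in the Protpars tradition charges an amino-acid
replacement the minimum number of single-nucleotide changes needed to get
from some codon of the first residue to some codon of the second, allowing
other amino acids (but not stop codons) as intermediates.  Formally: two
amino acids are adjacent iff some sense codon of one and some sense codon
of the other differ at exactly one nucleotide position; the cost is the
shortest-path length in that 20-node adjacency graph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .alignment import AMINO_ACIDS


@dataclass(frozen=True)
class CostMatrix:
    """Symmetric nonnegative integer substitution step costs.

    ``states`` is the fixed alphabetical amino-acid order; ``cost[i, j]``
    is the minimum step count from state i to state j.
    """

    states: str
    cost: np.ndarray

    def __post_init__(self) -> None:
        c = self.cost
        if c.shape != (len(self.states), len(self.states)):
            raise ValueError("cost matrix shape mismatch")
        if not np.array_equal(c, c.T):
            raise ValueError("cost matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("cost matrix diagonal must be zero")
        if np.any(c < 0):
            raise ValueError("costs must be nonnegative")
        # triangle inequality
        n = len(self.states)
        for k in range(n):
            through = c[:, k, None] + c[None, k, :]
            if np.any(c > through):
                raise ValueError("cost matrix violates the triangle inequality")

    def __getitem__(self, pair) -> int:
        a, b = pair
        return int(self.cost[self.states.index(a), self.states.index(b)])


def unit_cost_matrix() -> CostMatrix:
    """Fitch costs: every replacement counts one step."""
    n = len(AMINO_ACIDS)
    c = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
    return CostMatrix(AMINO_ACIDS, c)


def _sense_codons() -> dict[str, str]:
    """codon -> amino acid for the 61 sense codons of the standard code."""
    table = CodonTable.unambiguous_dna_by_id[1]
    return dict(table.forward_table)


def codon_adjacency() -> np.ndarray:
    """20x20 boolean: adjacent iff codons differ at exactly one position."""
    fwd = _sense_codons()
    n = len(AMINO_ACIDS)
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    adj = np.zeros((n, n), dtype=bool)
    codons = list(fwd)
    for c1 in codons:
        a1 = idx[fwd[c1]]
        for pos in range(3):
            for nt in "ACGT":
                if nt == c1[pos]:
                    continue
                c2 = c1[:pos] + nt + c1[pos + 1 :]
                if c2 in fwd:  # stop codons are not allowed as intermediates
                    a2 = idx[fwd[c2]]
                    if a1 != a2:
                        adj[a1, a2] = adj[a2, a1] = True
    return adj


@lru_cache(maxsize=1)
def genetic_code_cost_matrix() -> CostMatrix:
    """Shortest-path step costs over the genetic-code adjacency graph (BFS)."""
    adj = codon_adjacency()
    n = len(AMINO_ACIDS)
    cost = np.full((n, n), -1, dtype=int)
    for src in range(n):
        cost[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(adj[u]):
                if cost[src, v] < 0:
                    cost[src, v] = cost[src, u] + 1
                    q.append(v)
    if np.any(cost < 0):
        raise RuntimeError("genetic-code graph is not connected")  # pragma: no cover
    return CostMatrix(AMINO_ACIDS, cost)
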