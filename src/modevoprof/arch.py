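"""Domain-architecture comparison and gain/loss reconstruction.

The default evolutionary model is Dollo parsimony: a domain (protein
module) is gained once — at the last common ancestor of every species that
carries it — and may subsequently be lost on any number of lineages.  The
minimal loss set is found by a single post-order pass: an edge is a loss
iff its clade contains no presence leaf while its parent's clade does.
An unconstrained binary Fitch count is reported alongside as a baseline.

Presence values are 1 (present), 0 (absent) or -1 (unknown / unscanned:
ignored both in the gain-node computation and when asserting losses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ReferenceIdError, TreeShapeError
from .tree import PhyloTree

PRESENT, ABSENT, UNKNOWN_STATE = 1, 0, -1


@dataclass(frozen=True)
class ArchitectureMatrix:
    """Species x domain presence/absence matrix."""

    species: tuple[str, ...]
    domains: tuple[str, ...]
    presence: np.ndarray  # int8, values in {1, 0, -1}

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if len(set(self.domains)) != len(self.domains):
            raise ValueError("domain labels must be unique")
        if self.presence.shape != (len(self.species), len(self.domains)):
            raise ValueError("presence matrix shape mismatch")
        if not np.isin(self.presence, (PRESENT, ABSENT, UNKNOWN_STATE)).all():
            raise ValueError("presence entries must be 1, 0 or -1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArchitectureMatrix":
        return cls(
            tuple(str(s) for s in df.index),
            tuple(str(d) for d in df.columns),
            df.to_numpy(dtype=np.int8),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=list(self.species), columns=list(self.domains)
        )

    def row(self, species: str) -> dict[str, int]:
        try:
            i = self.species.index(species)
        except ValueError:
            raise ReferenceIdError(f"unknown species {species!r}") from None
        return dict(zip(self.domains, (int(v) for v in self.presence[i])))

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")


def read_architecture_table(path) -> ArchitectureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ArchitectureMatrix.from_frame(df)


@dataclass(frozen=True)
class GainLossScenario:
    """Dollo reconstruction of one domain on a species tree.

    ``gain_clade`` is the leafset of the gain node (None when the domain is
    absent everywhere); ``loss_edges`` are child-clade leafsets.
    """

    domain: str
    gain_clade: Optional[frozenset]
    gain_label: Optional[str]
    loss_edges: tuple[frozenset, ...]

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(
    mat: ArchitectureMatrix, tree: PhyloTree
) -> dict[str, GainLossScenario]:
    """Single-gain / multiple-loss reconstruction for every domain."""
    if not tree.is_rooted and len(tree.root.children) < 2:
        raise TreeShapeError("Dollo reconstruction requires a rooted tree")
    leaf_labels = set(tree.leaf_labels())
    missing = [s for s in mat.species if s not in leaf_labels]
    if missing:
        raise ReferenceIdError(f"species not in tree: {missing[:5]}")

    ls = tree.leafset_map()
    out: dict[str, GainLossScenario] = {}
    for d_idx, domain in enumerate(mat.domains):
        state = {
            sp: int(mat.presence[s_idx, d_idx])
            for s_idx, sp in enumerate(mat.species)
        }
        present = {sp for sp, v in state.items() if v == PRESENT}
        known = {sp for sp, v in state.items() if v != UNKNOWN_STATE}
        if not present:
            out[domain] = GainLossScenario(domain, None, None, ())
            continue
        gain = tree.mrca(present)
        gain_set = ls[id(gain)]
        losses: list[frozenset] = []
        # post-order below the gain node: mark an edge a loss iff its clade
        # has a known leaf but no presence leaf, and its parent clade still
        # has a presence leaf (otherwise the loss sits higher up)
        stack = list(gain.children)
        nodes = []
        while stack:
            n = stack.pop()
            nodes.append(n)
            stack.extend(n.children)
        for n in nodes:
            clade = ls[id(n)]
            if not (clade & present) and (clade & known):
                parent_clade = ls[id(n.parent)]
                if parent_clade & present:
                    losses.append(clade)
        losses.sort(key=lambda s: tuple(sorted(s)))
        out[domain] = GainLossScenario(domain, gain_set, gain.label, tuple(losses))
    return out


def scenario_presence(
    tree: PhyloTree, scenario: GainLossScenario
) -> dict[str, int]:
    """Replay a gain/loss scenario forward: presence value per leaf."""
    ls = tree.leafset_map()
    out: dict[str, int] = {}
    lost: frozenset = frozenset()
    for e in scenario.loss_edges:
        lost = lost | e
    for leaf in tree.leaves():
        if scenario.gain_clade is None or leaf.label not in scenario.gain_clade:
            out[leaf.label] = ABSENT
        elif leaf.label in lost:
            out[leaf.label] = ABSENT
        else:
            out[leaf.label] = PRESENT
    return out


def fitch_presence_changes(mat: ArchitectureMatrix, tree: PhyloTree) -> dict[str, int]:
    """Unconstrained binary Fitch change count per domain.

    Unknown leaves contribute the full state set {0, 1} (no information).
    """
    leaf_labels = set(tree.leaf_labels())
    missing = [s for s in mat.species if s not in leaf_labels]
    if missing:
        raise ReferenceIdError(f"species not in tree: {missing[:5]}")
    state_of = {sp: None for sp in leaf_labels}
    out: dict[str, int] = {}
    for d_idx, domain in enumerate(mat.domains):
        for s_idx, sp in enumerate(mat.species):
            state_of[sp] = int(mat.presence[s_idx, d_idx])
        changes = 0
        sets: dict[int, frozenset] = {}
        for node in tree.postorder():
            if node.is_leaf:
                v = state_of.get(node.label)
                if v is None or v == UNKNOWN_STATE:
                    sets[id(node)] = frozenset((0, 1))
                else:
                    sets[id(node)] = frozenset((v,))
            else:
                inter = None
                union: frozenset = frozenset()
                for c in node.children:
                    s = sets[id(c)]
                    inter = s if inter is None else inter & s
                    union |= s
                if inter:
                    sets[id(node)] = inter
                else:
                    # multifurcation-safe: count via majority-union rule
                    counts = {0: 0, 1: 0}
                    for c in node.children:
                        for v in sets[id(c)]:
                            counts[v] += 1
                    best = max(counts.values())
                    sets[id(node)] = frozenset(
                        v for v in (0, 1) if counts[v] == best
                    )
                    changes += len(node.children) - best
        out[domain] = changes
    return out


def compare_architectures(
    mat: ArchitectureMatrix, species_a: str, species_b: str
) -> tuple[set[str], set[str], set[str]]:
    """(shared, only_a, only_b) domain sets for two species rows.

    Unknown entries are treated as absent for the comparison.
    """
    ra, rb = mat.row(species_a), mat.row(species_b)
    a = {d for d, v in ra.items() if v == PRESENT}
    b = {d for d, v in rb.items() if v == PRESENT}
    return a & b, a - b, b - a


def scenarios_to_frame(scenarios: dict[str, GainLossScenario]) -> pd.DataFrame:
    rows = []
    for domain, sc in scenarios.items():
        rows.append(
            (
                domain,
                sc.gain_label
                or (",".join(sorted(sc.gain_clade)) if sc.gain_clade else "none"),
                ";".join(",".join(sorted(e)) for e in sc.loss_edges),
                sc.n_losses,
            )
        )
    return pd.DataFrame(rows, columns=["domain", "gain_node", "loss_edges", "n_losses"])
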