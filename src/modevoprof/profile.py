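"""Sliding-window substitution-rate profiles in reference coordinates.

A profile projects per-branch parsimony event counts onto the ungapped
residue positions of one named reference sequence (position 1 = start
methionine), restricted to a labeled subset of tree branches — e.g. "the
GASP1 subfamily" — and smooths the per-position counts with a moving
average (window 20 by default).  Windows shrink at the sequence termini
rather than padding: the divisor is always the number of real positions in
the window.  "Rate" here is a dimensionless parsimony event count per
site over the chosen branch set, not a per-unit-time rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import ColumnMap
from .domains import DomainAnnotationSet
from .errors import EmptyBranchSetError, IntervalError, ReferenceIdError, WindowError
from .parsimony import BranchCounts
from .tree import PhyloTree


@dataclass(frozen=True)
class BranchSet:
    """A labeled subset of tree edges, each named by its child-clade leafset."""

    label: str
    edges: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.edges:
            raise EmptyBranchSetError(f"branch set {self.label!r} has no edges")

    @classmethod
    def from_edge_leafsets(cls, label: str, leafsets, tree: PhyloTree) -> "BranchSet":
        known = set(tree.edge_ids())
        edges = tuple(frozenset(s) for s in leafsets)
        missing = [sorted(e) for e in edges if e not in known]
        if missing:
            raise ReferenceIdError(f"edges not in tree: {missing[:3]}")
        return cls(label, edges)

    @classmethod
    def from_clade(
        cls,
        label: str,
        tree: PhyloTree,
        clade_leaves,
        include_stem: bool = True,
    ) -> "BranchSet":
        """All edges inside the clade spanned by ``clade_leaves``
        (optionally including its stem edge)."""
        mrca = tree.mrca(clade_leaves)
        ls = tree.leafset_map()
        edges = []
        stack = list(mrca.children)
        while stack:
            n = stack.pop()
            edges.append(ls[id(n)])
            stack.extend(n.children)
        if include_stem and mrca.parent is not None:
            edges.append(ls[id(mrca)])
        return cls(label, tuple(edges))

    @classmethod
    def all_edges(cls, tree: PhyloTree, label: str = "all") -> "BranchSet":
        return cls(label, tuple(tree.edge_ids()))


@dataclass(frozen=True)
class RateProfile:
    """Per-reference-position substitution counts and their smoothed curve."""

    reference_id: str
    raw: np.ndarray  # (L,) counts at positions 1..L
    branch_set_tag: str
    smoothed: Optional[np.ndarray] = None
    window: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.raw)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.length + 1)

    def to_frame(self) -> pd.DataFrame:
        data = {"position": self.positions, "raw": self.raw}
        if self.smoothed is not None:
            data["smoothed"] = self.smoothed
        return pd.DataFrame(data)


def branch_subset_profile(
    bc: BranchCounts, bs: BranchSet, cmap: ColumnMap
) -> RateProfile:
    """Sum events of the chosen branches at each reference position.

    Columns where the reference row is gapped have no reference coordinate
    and are excluded.
    """
    rows = bc.rows_for(bs.edges)
    L = cmap.length
    raw = np.zeros(L, dtype=float)
    sub = bc.events[rows, :]
    for col, pos in cmap.col_to_pos.items():
        if col - 1 >= bc.n_cols:
            raise IntervalError(
                f"column map column {col} exceeds branch-count columns {bc.n_cols}"
            )
        raw[pos - 1] = sub[:, col - 1].sum()
    return RateProfile(
        reference_id=cmap.reference_id, raw=raw, branch_set_tag=bs.label
    )


def moving_average(profile: RateProfile, window: int = 20) -> RateProfile:
    """Centered moving average with truncated windows at the termini.

    Position *i* averages raw values over ``[i - floor(w/2),
    i + ceil(w/2) - 1]`` intersected with ``[1, L]``; the divisor is the
    actual number of positions in that intersection.
    """
    if window < 1:
        raise WindowError("window must be >= 1")
    L = profile.length
    if window > L:
        raise WindowError(f"window {window} exceeds profile length {L}")
    raw = profile.raw
    lo = window // 2
    hi = (window + 1) // 2  # ceil(w/2)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    smoothed = np.empty(L)
    for i in range(1, L + 1):
        a = max(1, i - lo)
        b = min(L, i + hi - 1)
        smoothed[i - 1] = (csum[b] - csum[a - 1]) / (b - a + 1)
    return replace(profile, smoothed=smoothed, window=window)


def per_domain_summary(
    profile: RateProfile, domains: DomainAnnotationSet
) -> pd.DataFrame:
    """Mean raw / smoothed rate per domain of the profile's reference.

    Positions outside every annotated domain are aggregated under
    ``linker``.  Columns: domain, n_positions, mean_raw, mean_smoothed.
    """
    L = profile.length
    intervals = domains.for_sequence(profile.reference_id)
    covered = np.zeros(L, dtype=bool)
    rows = []
    for iv in intervals:
        if iv.end > L:
            raise IntervalError(
                f"domain {iv.domain} interval end {iv.end} exceeds profile "
                f"length {L}"
            )
        mask = np.zeros(L, dtype=bool)
        mask[iv.start - 1 : iv.end] = True
        covered |= mask
        rows.append((iv.domain, mask))
    merged: dict[str, np.ndarray] = {}
    for name, mask in rows:
        merged[name] = merged.get(name, np.zeros(L, dtype=bool)) | mask
    out = []
    for name, mask in merged.items():
        out.append(_summary_row(name, mask, profile))
    linker = ~covered
    if linker.any():
        out.append(_summary_row("linker", linker, profile))
    return pd.DataFrame(
        out, columns=["domain", "n_positions", "mean_raw", "mean_smoothed"]
    )


def _summary_row(name: str, mask: np.ndarray, profile: RateProfile):
    n = int(mask.sum())
    mean_raw = float(profile.raw[mask].mean())
    mean_sm = (
        float(profile.smoothed[mask].mean()) if profile.smoothed is not None else np.nan
    )
    return (name, n, mean_raw, mean_sm)


def write_profile_tsv(
    profile: RateProfile, domains: DomainAnnotationSet | None, path, params: dict | None = None
) -> None:
    """Profile TSV: position, raw, smoothed, domain (with '#' parameter header)."""
    df = profile.to_frame()
    labels = np.array([""] * profile.length, dtype=object)
    if domains is not None:
        for iv in domains.for_sequence(profile.reference_id):
            labels[iv.start - 1 : min(iv.end, profile.length)] = iv.domain
    df["domain"] = labels
    with open(path, "w") as fh:
        fh.write(f"# reference={profile.reference_id} branch_set={profile.branch_set_tag} "
                 f"window={profile.window}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
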