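"""Sliding-window paralogon detection between two gene orders.

A paralogon is a pair of chromosomal segments retaining several paralogous
gene pairs from an ancient (whole-genome) duplication.  Gene positions are
ordinal indices (1-based), not base-pair coordinates — the window unit is
"genes", matching the 50–100-gene windows used for this kind of scan.

A window of ``window`` consecutive positions slides over each chromosome
(step 1); a window pair qualifies when at least ``min_pairs`` distinct
paralog pairs have one member in each window, counting each gene in at
most one pair (greedy left-to-right matching, which keeps tandem arrays
from inflating the count).  Overlapping qualifying window pairs are merged
(2-D interval merge) into maximal hits whose ranges are trimmed to the
outermost contributing genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import WindowError


@dataclass(frozen=True)
class GeneOrder:
    chromosome: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene ids on {self.chromosome}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes, start=1)}


@dataclass(frozen=True)
class ParalogyMap:
    pairs: frozenset  # of frozenset({gene_a, gene_b})

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"self-pair or malformed pair {set(p)}")

    @classmethod
    def from_pairs(cls, pairs) -> "ParalogyMap":
        return cls(frozenset(frozenset(p) for p in pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ParalogonHit:
    range_a: tuple[int, int]
    range_b: tuple[int, int]
    pair_count: int
    anchor_pairs: tuple[tuple[str, str], ...]  # (gene on A, gene on B)


def read_gene_order(path, chromosome: str | None = None) -> GeneOrder:
    """Two-column TSV (position, gene_id), sorted by position on read."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("gene order table must have 2 columns")
    try:
        int(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    df = df.assign(pos=df[0].astype(int)).sort_values("pos")
    return GeneOrder(chromosome or "chr", tuple(df[1].astype(str)))


def read_pair_table(path) -> ParalogyMap:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    try:
        pairs = [(str(a), str(b)) for a, b in zip(df[0], df[1])]
    except KeyError:
        raise ValueError("pair table must have 2 columns") from None
    if pairs and pairs[0] == ("gene_a", "gene_b"):
        pairs = pairs[1:]
    return ParalogyMap.from_pairs(pairs)


def _anchors(a: GeneOrder, b: GeneOrder, pmap: ParalogyMap):
    """(pos_a, pos_b, gene_a, gene_b) for every pair with one member per side."""
    pa, pb = a.positions, b.positions
    out = []
    for pair in pmap.pairs:
        x, y = tuple(pair)
        for g1, g2 in ((x, y), (y, x)):
            if g1 in pa and g2 in pb:
                out.append((pa[g1], pb[g2], g1, g2))
    out.sort()
    return out


def _greedy_count(anchors) -> list:
    """Greedy left-to-right matching: each gene in at most one pair."""
    used_a: set[str] = set()
    used_b: set[str] = set()
    kept = []
    for pos_a, pos_b, ga, gb in sorted(anchors):
        if ga in used_a or gb in used_b:
            continue
        used_a.add(ga)
        used_b.add(gb)
        kept.append((pos_a, pos_b, ga, gb))
    return kept


def scan(
    a: GeneOrder,
    b: GeneOrder,
    pmap: ParalogyMap,
    window: int = 50,
    min_pairs: int = 3,
) -> list[ParalogonHit]:
    """Detect paralogons between two chromosomes."""
    if window < 1 or min_pairs < 1:
        raise ValueError("window and min_pairs must be >= 1")
    if window > len(a) or window > len(b):
        raise WindowError(
            f"window {window} exceeds a chromosome length "
            f"({len(a)} / {len(b)} genes)"
        )
    anchors = _anchors(a, b, pmap)
    if not anchors:
        return []

    pa = np.array([x[0] for x in anchors])
    pb = np.array([x[1] for x in anchors])
    max_i = len(a) - window + 1
    max_j = len(b) - window + 1

    # candidate A-window starts: only windows containing >= 1 anchor
    cand_i: set[int] = set()
    for p in np.unique(pa):
        cand_i.update(range(max(1, p - window + 1), min(p, max_i) + 1))

    rects: list[tuple[int, int]] = []  # qualifying (i, j) window starts
    for i in sorted(cand_i):
        in_a = (pa >= i) & (pa <= i + window - 1)
        if int(in_a.sum()) < min_pairs:
            continue
        sub = [anchors[k] for k in np.flatnonzero(in_a)]
        sub_pb = np.sort(pb[in_a])
        cand_j: set[int] = set()
        for p in sub_pb:
            cand_j.update(range(max(1, int(p) - window + 1), min(int(p), max_j) + 1))
        cand_j_arr = np.fromiter(sorted(cand_j), dtype=int)
        # distinct-anchor upper bound for every candidate j at once
        n_raw = np.searchsorted(sub_pb, cand_j_arr + window - 1, side="right") - np.searchsorted(
            sub_pb, cand_j_arr, side="left"
        )
        for j in cand_j_arr[n_raw >= min_pairs]:
            boxed = [t for t in sub if j <= t[1] <= j + window - 1]
            if len(_greedy_count(boxed)) >= min_pairs:
                rects.append((int(i), int(j)))

    if not rects:
        return []

    # collapse consecutive-j runs at each i into single rectangles
    # [i, i+w-1] x [js, je+w-1], then merge overlapping rectangles
    runs: list[tuple[int, int, int, int]] = []  # (i_lo, i_hi, j_lo, j_hi)
    by_i: dict[int, list[int]] = {}
    for i, j in rects:
        by_i.setdefault(i, []).append(j)
    for i, js in by_i.items():
        js.sort()
        start = prev = js[0]
        for j in js[1:] + [None]:
            if j is not None and j == prev + 1:
                prev = j
                continue
            runs.append((i, i + window - 1, start, prev + window - 1))
            if j is not None:
                start = prev = j
    hits = []
    for comp in _merge_runs(runs):
        in_comp = [
            t
            for t in anchors
            if any(
                r[0] <= t[0] <= r[1] and r[2] <= t[1] <= r[3] for r in comp
            )
        ]
        matched = _greedy_count(in_comp)
        if len(matched) < min_pairs:
            continue
        ra = (min(t[0] for t in matched), max(t[0] for t in matched))
        rb = (min(t[1] for t in matched), max(t[1] for t in matched))
        hits.append(
            ParalogonHit(
                range_a=ra,
                range_b=rb,
                pair_count=len(matched),
                anchor_pairs=tuple((t[2], t[3]) for t in matched),
            )
        )
    hits.sort(key=lambda h: (h.range_a, h.range_b))
    return hits


def _merge_runs(runs: list[tuple[int, int, int, int]]):
    """Connected components of rectangles (i_lo, i_hi, j_lo, j_hi) under
    2-D overlap."""
    parent = list(range(len(runs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for x in range(len(runs)):
        a = runs[x]
        for y in range(x + 1, len(runs)):
            b = runs[y]
            if a[0] <= b[1] and b[0] <= a[1] and a[2] <= b[3] and b[2] <= a[3]:
                parent[find(x)] = find(y)
    comps: dict[int, list[tuple[int, int, int, int]]] = {}
    for k, r in enumerate(runs):
        comps.setdefault(find(k), []).append(r)
    return list(comps.values())


def anchor_report(hits: list[ParalogonHit], gene_id: str) -> list[ParalogonHit]:
    """Hits in which ``gene_id`` contributes an anchor pair."""
    return [
        h
        for h in hits
        if any(gene_id in pair for pair in h.anchor_pairs)
    ]


def hits_to_frame(hits: list[ParalogonHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                h.range_a[0],
                h.range_a[1],
                h.range_b[0],
                h.range_b[1],
                h.pair_count,
                ";".join(f"{x}|{y}" for x, y in h.anchor_pairs),
            )
            for h in hits
        ],
        columns=["a_start", "a_end", "b_start", "b_end", "pair_count", "anchor_pairs"],
    )
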