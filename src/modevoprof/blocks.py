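"""Conserved-block selection from protein alignments.

Selects the reliably aligned column blocks of an alignment by per-column
conservation and block-length rules, in the style of Gblocks.  Two presets
are shipped: ``relaxed`` (the "less stringent" option family: conservation
thresholds at a simple majority, gaps tolerated in under half the rows,
minimum block length 5) and ``strict`` (85% flank conservation, no gaps,
minimum block length 10).  Exact byte-compatibility with any particular
Gblocks build is not claimed; the rules below are the documented
algorithm restated.

Column statuses
---------------
A column is

* ``nonconserved`` if its gap policy is violated, or the count of its most
  frequent residue (gaps and ``X`` never count as residues) is below
  ``min_seqs_conserved``;
* ``highly_conserved`` if that count is at least ``min_seqs_flank``;
* ``conserved`` otherwise.

Block selection then (1) excises every run of more than
``max_contig_nonconserved`` consecutive nonconserved columns, (2) trims
each remaining segment so that its first and last columns are highly
conserved, and (3) drops segments shorter than ``min_block_len``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import GAP, UNKNOWN, ProteinAlignment

NONCONSERVED, CONSERVED, HIGHLY_CONSERVED = 0, 1, 2
STATUS_NAMES = {0: "nonconserved", 1: "conserved", 2: "highly_conserved"}

GAP_POLICIES = ("none", "with_half", "all")


@dataclass(frozen=True)
class BlockParams:
    min_seqs_conserved: int
    min_seqs_flank: int
    max_contig_nonconserved: int = 8
    min_block_len: int = 5
    gap_policy: str = "with_half"

    def __post_init__(self) -> None:
        if self.min_seqs_conserved < 1 or self.min_seqs_flank < 1:
            raise ValueError("conservation thresholds must be >= 1")
        if self.min_seqs_flank < self.min_seqs_conserved:
            raise ValueError("min_seqs_flank must be >= min_seqs_conserved")
        if self.max_contig_nonconserved < 1 or self.min_block_len < 1:
            raise ValueError("block parameters must be >= 1")
        if self.gap_policy not in GAP_POLICIES:
            raise ValueError(f"gap_policy must be one of {GAP_POLICIES}")


def relaxed_params(n_seqs: int) -> BlockParams:
    """The "less stringent" preset (simple-majority thresholds)."""
    maj = n_seqs // 2 + 1
    return BlockParams(
        min_seqs_conserved=maj,
        min_seqs_flank=maj,
        max_contig_nonconserved=8,
        min_block_len=5,
        gap_policy="with_half",
    )


def strict_params(n_seqs: int) -> BlockParams:
    maj = n_seqs // 2 + 1
    return BlockParams(
        min_seqs_conserved=maj,
        min_seqs_flank=max(maj, math.ceil(0.85 * n_seqs)),
        max_contig_nonconserved=8,
        min_block_len=10,
        gap_policy="none",
    )


PRESETS = {"relaxed": relaxed_params, "strict": strict_params}


@dataclass(frozen=True)
class BlockSelection:
    """Selected blocks in original 1-based column numbering."""

    kept_columns: tuple[int, ...]
    blocks: tuple[tuple[int, int], ...]
    params: BlockParams

    def apply(self, aln: ProteinAlignment) -> ProteinAlignment:
        return aln.take_columns(self.kept_columns)

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("block\tstart_col\tend_col\tlength\n")
            for i, (s, e) in enumerate(self.blocks, start=1):
                fh.write(f"{i}\t{s}\t{e}\t{e - s + 1}\n")


def classify_columns(aln: ProteinAlignment, params: BlockParams) -> np.ndarray:
    """Per-column status array (values NONCONSERVED/CONSERVED/HIGHLY_CONSERVED)."""
    arr = aln.to_array()
    n, C = arr.shape
    gaps = (arr == GAP).sum(axis=0)
    residue = (arr != GAP) & (arr != UNKNOWN)
    statuses = np.empty(C, dtype=np.int8)
    for c in range(C):
        if params.gap_policy == "none" and gaps[c] > 0:
            statuses[c] = NONCONSERVED
            continue
        if params.gap_policy == "with_half" and gaps[c] >= 0.5 * n:
            statuses[c] = NONCONSERVED
            continue
        col = arr[residue[:, c], c]
        top = 0
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            top = int(counts.max())
        if top < params.min_seqs_conserved:
            statuses[c] = NONCONSERVED
        elif top >= params.min_seqs_flank:
            statuses[c] = HIGHLY_CONSERVED
        else:
            statuses[c] = CONSERVED
    return statuses


def select_blocks(statuses: np.ndarray, params: BlockParams) -> BlockSelection:
    statuses = np.asarray(statuses)
    C = len(statuses)
    excised = np.zeros(C, dtype=bool)

    # (1) excise long runs of nonconserved columns
    c = 0
    while c < C:
        if statuses[c] == NONCONSERVED:
            start = c
            while c < C and statuses[c] == NONCONSERVED:
                c += 1
            if c - start > params.max_contig_nonconserved:
                excised[start:c] = True
        else:
            c += 1

    # segments of surviving columns
    blocks: list[tuple[int, int]] = []
    c = 0
    while c < C:
        if excised[c]:
            c += 1
            continue
        start = c
        while c < C and not excised[c]:
            c += 1
        end = c  # exclusive
        # (2) trim to highly conserved flanks
        while start < end and statuses[start] != HIGHLY_CONSERVED:
            start += 1
        while end > start and statuses[end - 1] != HIGHLY_CONSERVED:
            end -= 1
        # (3) length filter
        if end - start >= params.min_block_len:
            blocks.append((start + 1, end))  # 1-based inclusive

    kept = tuple(
        col for (s, e) in blocks for col in range(s, e + 1)
    )
    return BlockSelection(kept_columns=kept, blocks=tuple(blocks), params=params)


def filter_alignment(
    aln: ProteinAlignment, params: BlockParams | None = None, preset: str = "relaxed"
) -> tuple[ProteinAlignment | None, BlockSelection]:
    """Classify, select, and apply in one call.

    Returns ``(filtered_alignment, selection)``; the alignment is ``None``
    when no block survives.
    """
    if params is None:
        params = PRESETS[preset](aln.n_seqs)
    statuses = classify_columns(aln, params)
    sel = select_blocks(statuses, params)
    sub = sel.apply(aln) if sel.kept_columns else None
    return sub, sel
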