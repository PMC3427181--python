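"""Protein alignments and the alignment-column / residue-coordinate bookkeeping.

The in-memory container is a small immutable :class:`ProteinAlignment` over
the 20 amino acids plus ``-`` (gap) and ``X`` (unknown residue).  All
coordinates in this package are 1-based inclusive: alignment columns run
1..n_cols, and ungapped residue positions run 1..L counted from the
start-methionine (position 1 = first residue of the unaligned sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentFormatError,
    AlphabetError,
    DuplicateIdError,
    ReferenceIdError,
)

#: Canonical one-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned set of protein sequences.

    Parameters
    ----------
    ids
        Unique sequence identifiers, in input order.
    rows
        Aligned sequences, one per id, all of equal length, over the
        20 amino acids plus ``-`` and ``X``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise AlignmentFormatError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            seen, dup = set(), None
            for i in self.ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise DuplicateIdError(f"duplicate sequence id {dup!r}")
        n = len(self.rows[0])
        if n < 1:
            raise AlignmentFormatError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise AlignmentFormatError(
                    f"row {sid!r} has length {len(row)}, expected {n}"
                )
            bad = set(row) - _ALPHABET
            if bad:
                sym = sorted(bad)[0]
                raise AlphabetError(
                    f"illegal symbol {sym!r} in record {sid!r}"
                )

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise ReferenceIdError(f"unknown sequence id {seq_id!r}") from None

    def ungapped_length(self, seq_id: str) -> int:
        return sum(1 for c in self.row(seq_id) if c != GAP)

    def to_array(self) -> np.ndarray:
        """Return an (n_seqs, n_cols) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="<U1")

    def take_columns(self, columns) -> "ProteinAlignment":
        """Sub-alignment of the given 1-based columns (order preserved,
        repeats allowed — bootstrap resampling uses repeats)."""
        idx = [c - 1 for c in columns]
        if not idx:
            raise AlignmentFormatError("cannot take zero columns")
        for c in idx:
            if c < 0 or c >= self.n_cols:
                raise IndexError(f"column {c + 1} out of range 1..{self.n_cols}")
        rows = tuple("".join(r[c] for c in idx) for r in self.rows)
        return ProteinAlignment(self.ids, rows)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")


def read_alignment(path, format: str = "fasta") -> ProteinAlignment:
    """Read an aligned FASTA file.

    Lowercase residues are uppercased and ``.`` gaps normalized to ``-``
    before validation.
    """
    if format != "fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", GAP))
    if not ids:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    return ProteinAlignment(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class ColumnMap:
    """Map from alignment columns to ungapped positions of one reference row.

    ``col_to_pos`` is defined exactly on the columns where the reference is
    not gapped; positions are consecutive 1..L from the start-methionine.
    """

    reference_id: str
    col_to_pos: dict[int, int] = field(hash=False)

    @property
    def length(self) -> int:
        """Ungapped length L of the reference."""
        return len(self.col_to_pos)

    @property
    def pos_to_col(self) -> dict[int, int]:
        return {p: c for c, p in self.col_to_pos.items()}


def build_column_map(aln: ProteinAlignment, reference_id: str) -> ColumnMap:
    """Map alignment columns onto the ungapped coordinates of one sequence.

    An ``X`` counts as a residue (it occupies a position); only ``-`` is
    skipped.  An all-gap reference yields an empty map.
    """
    row = aln.row(reference_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            pos += 1
            mapping[col] = pos
    if not mapping:
        import warnings

        warnings.warn(
            f"reference {reference_id!r} is all gaps; empty column map",
            stacklevel=2,
        )
    return ColumnMap(reference_id, mapping)
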