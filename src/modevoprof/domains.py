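"""Per-sequence protein-domain annotations.

Domain intervals use 1-based inclusive *ungapped* residue coordinates, as
produced by domain scanners run on the unaligned sequences (signal peptide,
WAP, follistatin, kazal, IGc2, kunitz, NTR modules in the motivating
family).  Intervals for one sequence may not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import IntervalError, OverlapError


@dataclass(frozen=True)
class DomainInterval:
    seq_id: str
    domain: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise IntervalError(
                f"{self.seq_id}/{self.domain}: invalid interval "
                f"[{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class DomainAnnotationSet:
    entries: tuple[DomainInterval, ...]

    def __post_init__(self) -> None:
        by_seq: dict[str, list[DomainInterval]] = {}
        for e in self.entries:
            by_seq.setdefault(e.seq_id, []).append(e)
        for sid, ivs in by_seq.items():
            ivs = sorted(ivs, key=lambda e: e.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise OverlapError(
                        f"{sid}: domains {a.domain} [{a.start},{a.end}] and "
                        f"{b.domain} [{b.start},{b.end}] overlap"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def for_sequence(self, seq_id: str) -> tuple[DomainInterval, ...]:
        return tuple(
            sorted(
                (e for e in self.entries if e.seq_id == seq_id),
                key=lambda e: e.start,
            )
        )

    def domain_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.domain, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.seq_id, e.domain, e.start, e.end) for e in self.entries],
            columns=["seq_id", "domain", "start", "end"],
        )

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_domain_table(path) -> DomainAnnotationSet:
    """Read a 4-column TSV (seq_id, domain, start, end); header optional."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        warnings.warn(f"domain table {path} is empty", stacklevel=2)
        return DomainAnnotationSet(())
    if df.shape[1] != 4:
        raise IntervalError(
            f"domain table must have 4 columns, got {df.shape[1]}"
        )
    first = df.iloc[0]
    try:
        int(first[2]), int(first[3])
    except (TypeError, ValueError):
        df = df.iloc[1:]  # header line
    if df.empty:
        warnings.warn(f"domain table {path} has a header only", stacklevel=2)
        return DomainAnnotationSet(())
    entries = tuple(
        DomainInterval(str(r[0]), str(r[1]), int(r[2]), int(r[3]))
        for r in df.itertuples(index=False)
    )
    return DomainAnnotationSet(entries)


def validate_against_alignment(domains: DomainAnnotationSet, aln) -> None:
    """Check every interval fits within the ungapped length of its sequence."""
    for e in domains.entries:
        L = aln.ungapped_length(e.seq_id)
        if e.end > L:
            raise IntervalError(
                f"{e.seq_id}/{e.domain}: end {e.end} exceeds ungapped "
                f"length {L}"
            )
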