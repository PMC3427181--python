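"""Pairwise protein distances with Poisson or gamma rate correction.

Distances use pairwise deletion: for each sequence pair, only columns where
both sequences carry a residue (not ``-`` or ``X``) are compared.  With
observed proportion of differing sites *p*:

* ``p``       — uncorrected p-distance,
* ``poisson`` — d = −ln(1 − p),
* ``gamma``   — d = α·((1 − p)^(−1/α) − 1), the gamma-rates correction
  standing in for "+G" style among-site rate variation (α → ∞ recovers the
  Poisson correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment import GAP, UNKNOWN, ProteinAlignment
from .errors import CoverageError, SaturationError

MODELS = ("p", "poisson", "gamma")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray
    model_tag: str
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        d = self.d
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite and nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)


def correct_p(p: float, model: str, alpha: float) -> float:
    if model == "p":
        return p
    if p >= 1.0:
        raise SaturationError("p = 1 cannot be corrected")
    if model == "poisson":
        return -np.log1p(-p)
    if model == "gamma":
        return alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
    raise ValueError(f"unknown model {model!r}")


def pairwise_distances(
    aln: ProteinAlignment, model: str = "gamma", alpha: float = 1.0
) -> DistanceMatrix:
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if model == "gamma" and not (alpha > 0):
        raise ValueError("alpha must be positive")
    n = aln.n_seqs
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = aln.to_array()
    valid = (arr != GAP) & (arr != UNKNOWN)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise CoverageError(
                    f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "compared columns"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            try:
                d[i, j] = d[j, i] = correct_p(p, model, alpha)
            except SaturationError:
                raise SaturationError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) is saturated "
                    f"(p = 1) under model {model!r}"
                ) from None
    return DistanceMatrix(
        tuple(aln.ids), d, model_tag=model, alpha=alpha if model == "gamma" else None
    )
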