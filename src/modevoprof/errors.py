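"""Exception hierarchy.

Every error raised on invalid user input derives from :class:`EvoProfError`
so callers (and the CLI) can distinguish bad data from bugs.
"""


class EvoProfError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(EvoProfError):
    """Rows of unequal length, empty input, or otherwise malformed alignment."""


class DuplicateIdError(EvoProfError):
    """A sequence or leaf identifier occurs more than once."""


class AlphabetError(EvoProfError):
    """A residue symbol outside the accepted alphabet."""


class IntervalError(EvoProfError):
    """A domain interval with start > end or exceeding the sequence length."""


class OverlapError(EvoProfError):
    """Two domain intervals on one sequence overlap."""


class NewickParseError(EvoProfError):
    """Unbalanced or otherwise unparsable Newick input."""


class ReferenceIdError(EvoProfError, KeyError):
    """A named sequence / leaf / node is not present."""


class SaturationError(EvoProfError):
    """A pairwise distance is undefined (p = 1) under the chosen correction."""


class CoverageError(EvoProfError):
    """A sequence pair shares no ungapped column."""


class TreeShapeError(EvoProfError):
    """Tree does not have the shape an operation requires."""


class WindowError(EvoProfError):
    """Sliding-window size incompatible with the data."""


class EmptyBranchSetError(EvoProfError):
    """A branch subset with no edges."""


class BootstrapFailureError(EvoProfError):
    """Too many bootstrap replicates had to be discarded."""


class ConfigError(EvoProfError):
    """Invalid simulation or pipeline configuration."""
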