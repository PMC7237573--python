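"""Named errors raised across the package.

Every error a caller is expected to catch derives from :class:`IenetError`,
which itself derives from ``ValueError`` so that careless callers still fail
loudly rather than silently.
"""


class IenetError(ValueError):
    """Base class for all package-specific errors."""


class GeneLengthError(IenetError):
    """A gene length is missing, zero, or negative."""


class EmptySampleError(IenetError):
    """A sample column is all zero and cannot be closed to sum one."""


class DuplicateIdError(IenetError):
    """Duplicate taxon, gene, or sample identifiers."""


class TableFormatError(IenetError):
    """A TSV table is ragged, non-numeric, or otherwise malformed."""


class AnnotationError(IenetError):
    """Gene annotation map is empty or inconsistent."""


class GroupError(IenetError):
    """A requested group is absent from the design or too small."""


class ReferenceSizeError(IenetError):
    """Too few reference samples to fit a correlation model."""


class MarkerError(IenetError):
    """A marker set is empty, not a strict subset, or otherwise unusable."""


class CoverageError(IenetError):
    """Required sPCC values are unavailable for some taxon pairs."""


class NotClosedError(IenetError):
    """An operation requires compositionally closed (sum-to-one) columns."""


class SimulationError(IenetError):
    """Invalid synthetic-cohort specification (e.g. non-PSD correlation)."""
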