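"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`MinishapeError`, so callers can catch one type at pipeline
boundaries while still discriminating failure modes.
"""


class MinishapeError(Exception):
    """Base class for all package errors."""


class SpecificationError(MinishapeError, ValueError):
    """An input specification is internally inconsistent (overlapping
    segments, bad junction counts, empty tables, missing reference design)."""


class RangeError(MinishapeError, IndexError):
    """A position lies outside the sequence or construct it refers to."""


class AlphabetError(MinishapeError, ValueError):
    """A sequence contains characters outside the RNA alphabet ACGU."""


class StateError(MinishapeError, ValueError):
    """An operation was applied to a profile or construct in the wrong
    processing state (e.g. normalizing twice, flanking a flanked construct)."""


class AlignmentError(MinishapeError, ValueError):
    """Two per-position datasets that must share a coordinate frame do not."""


class MappingError(MinishapeError, KeyError):
    """A native label has no image in the construct (excised residue)."""


class ConsistencyError(MinishapeError, ValueError):
    """Observed sequence content contradicts a declared wild-type base."""


class ParseError(MinishapeError, ValueError):
    """Malformed mutation notation or file content."""


class NormalizationError(MinishapeError, ValueError):
    """Reference-hairpin mean is non-positive or otherwise unusable."""


class DegeneracyError(MinishapeError, ValueError):
    """A statistic is undefined on the given data (constant profile,
    zero variance, too few complete pairs)."""


class StructureError(MinishapeError, ValueError):
    """A dot-bracket string is unbalanced or of the wrong length."""
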