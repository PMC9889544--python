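"""Exception hierarchy for nirsleep.

All errors raised by the package derive from :class:`NirsError`, so callers can
catch one base class. The subclasses mirror the failure modes of the analysis:
structural problems in a probe description, dimension/shape mismatches, invalid
parameters, bad data values, numerical conditioning, and group-selection errors.
"""


class NirsError(Exception):
    """Base class for all nirsleep errors."""


class StructuralError(NirsError, ValueError):
    """A montage/probe description is internally inconsistent
    (dangling optode references, duplicate ids, ...)."""


class PairingError(NirsError, ValueError):
    """Homotopic pairing is undefined for the requested montage or matrix."""


class DimensionError(NirsError, ValueError):
    """Array shapes or grids do not match the operation's contract."""


class ParameterError(NirsError, ValueError):
    """A parameter value is outside the operation's admissible range."""


class DomainError(NirsError, ValueError):
    """Input values are outside the mathematical domain of the operation
    (e.g. non-positive light intensity under a logarithm)."""


class DataError(NirsError, ValueError):
    """Input data are malformed (non-finite samples, missing chromophore, ...)."""


class ConditioningError(NirsError, ValueError):
    """A linear system is singular or too ill-conditioned to invert reliably."""


class CollinearityError(NirsError, ValueError):
    """A regression design matrix is rank deficient."""


class GroupingError(NirsError, ValueError):
    """A group comparison was requested with an empty or one-sided grouping."""


class SampleSizeError(NirsError, ValueError):
    """Too few subjects for the requested statistical test."""


class CohortSpecError(NirsError, ValueError):
    """A synthetic cohort specification is invalid."""


class ChromophoreError(NirsError, TypeError):
    """An operation received data for the wrong chromophore pair."""


class InputError(NirsError, ValueError):
    """A file or directory input is missing or inconsistent."""
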