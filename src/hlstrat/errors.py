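"""Exception hierarchy shared across the package."""


class HLStratError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HLStratError, ValueError):
    """An input violates a documented precondition."""


class DuplicateKeyError(ValidationError):
    """A (sample, marker) or sample identifier occurs more than once."""


class EmptyCohortError(ValidationError):
    """An operation that needs at least one record received none."""


class InsufficientDataError(HLStratError):
    """Too few fitted points for the requested number of free parameters."""


class UnmergeableGroupingError(HLStratError):
    """Small-group merging cannot produce groups of the required size."""


class EmptyOverlapError(HLStratError):
    """A gene set shares no genes with the expression universe."""


class DegenerateInputError(HLStratError):
    """Zero-variance or otherwise degenerate numeric input."""
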