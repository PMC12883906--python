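"""Exception hierarchy shared across the package."""


class AlgaecastError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AlgaecastError):
    """A file or table does not have the expected structure (e.g. missing column)."""


class DataError(AlgaecastError):
    """Values violate a series invariant (duplicate/non-monotonic timestamps, gaps)."""


class DomainError(AlgaecastError, ValueError):
    """An argument is outside the physically or mathematically valid domain."""
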