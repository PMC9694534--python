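"""Exception hierarchy shared across the package."""


class WibsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WibsError, ValueError):
    """A file or table does not conform to the expected schema."""


class ValidationError(WibsError, ValueError):
    """A value violates a physical or structural invariant."""


class InsufficientDataError(WibsError, ValueError):
    """Not enough records to perform the requested computation."""


class ConfigurationError(WibsError, ValueError):
    """Inconsistent or invalid configuration of an analysis step."""
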