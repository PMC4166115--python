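"""Exception hierarchy shared across the package."""


class DualstressError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(DualstressError, ValueError):
    """Invalid parameter value (non-positive count, negative SD, ...)."""


class ValidationError(DualstressError, ValueError):
    """Input data violates a documented invariant."""


class FormatError(DualstressError, ValueError):
    """A file does not match the expected tabular layout."""
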