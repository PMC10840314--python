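"""Exception types shared across saskit."""


class SasKitError(Exception):
    """Base class for all saskit errors."""


class FormatError(SasKitError, ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(SasKitError, ValueError):
    """Inputs violate a documented precondition or invariant."""
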