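"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a documented invariant (bad interval, negative rate, ...)."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line where possible."""
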