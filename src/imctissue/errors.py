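"""Package-specific exception types."""


class InvalidParameterError(ValueError):
    """A physical or configuration parameter violates its constraints."""


class InvalidMeasurementError(ValueError):
    """A measured quantity is outside its physically admissible range."""
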