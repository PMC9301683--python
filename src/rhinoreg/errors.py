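"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration object violates one of its invariants."""


class ValidationError(ValueError):
    """Input data violate a precondition (e.g. mixed patients, unsorted dates)."""
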