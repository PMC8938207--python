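"""Exception types shared across the pipeline stages."""


class ValidationError(ValueError):
    """Raised when an input file or record violates the data contract."""


class ConfigurationError(ValueError):
    """Raised when a run or cohort configuration is invalid; names the offending field."""
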