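"""Exception hierarchy."""


class ElastiGateError(Exception):
    """Base class for package errors."""


class ConfigurationError(ElastiGateError):
    """A run configuration or template references something that does not exist."""


class InputError(ElastiGateError):
    """Invalid input data (dimension mismatch, singular spillover, ...)."""


class SchemaError(ElastiGateError):
    """Gate-template file violates the schema or its invariants."""
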