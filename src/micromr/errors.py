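"""Exception hierarchy shared across micromr modules."""


class MicroMRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MicroMRError):
    """A required column is missing or a file header is malformed."""


class ValidationError(MicroMRError):
    """Input data violates a structural invariant (e.g. duplicate ids)."""


class DomainError(MicroMRError):
    """An argument is outside the mathematical domain of an operation."""


class UsageError(MicroMRError):
    """An operation was called with inconsistent or empty inputs."""
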