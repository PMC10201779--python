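"""Exception hierarchy shared across the package."""


class SigrevError(Exception):
    """Base class for all package errors."""


class ParameterError(SigrevError):
    """An argument is outside its documented domain."""


class SizingError(SigrevError):
    """A simulation request does not fit in the configured gene universe."""


class QueryError(SigrevError):
    """A connectivity or enrichment query is empty or not contained in its universe."""


class SignatureSizeError(SigrevError):
    """A disease signature cannot be built (no genes pass the filters)."""


class ParseError(SigrevError):
    """An on-disk input violates its documented schema."""


class ConfigError(SigrevError):
    """A run configuration contains unknown keys or out-of-domain values."""


class DomainError(SigrevError):
    """A score is outside its mathematically valid range."""
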