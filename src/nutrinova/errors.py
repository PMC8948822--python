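"""Exception hierarchy for databank loading, configuration and analysis."""


class NutrinovaError(Exception):
    """Base class for all package errors."""


class SchemaError(NutrinovaError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(NutrinovaError):
    """A row violates a databank invariant (raised on load; see validate_item)."""


class ConfigError(NutrinovaError):
    """An analysis or generator configuration is internally inconsistent."""


class DomainError(NutrinovaError):
    """An operation was called outside its mathematical domain (e.g. energy <= 0)."""
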