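"""Exception hierarchy shared across the package."""


class Fcs3cError(Exception):
    """Base class for all package-specific errors."""


class DomainError(Fcs3cError, ValueError):
    """A physical parameter is outside its admissible domain."""


class ConfigurationError(Fcs3cError, ValueError):
    """A required configuration item is missing or inconsistent."""


class SchemaError(Fcs3cError, ValueError):
    """An input file or table does not match the expected schema."""


class FitError(Fcs3cError, RuntimeError):
    """A fit cannot even be attempted (degenerate or invalid input)."""
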