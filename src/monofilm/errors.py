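"""Exception hierarchy for monofilm."""


class MonofilmError(Exception):
    """Base class for all package-specific errors."""


class IsothermFormatError(MonofilmError, ValueError):
    """Raised when an isotherm file cannot be parsed."""


class DegenerateIsothermError(MonofilmError, ValueError):
    """Raised when too few points survive canonicalization to be usable."""


class OutOfRangeError(MonofilmError, ValueError):
    """Raised when a requested surface pressure lies outside the recorded range."""


class ParameterError(MonofilmError, ValueError):
    """Raised for invalid user-supplied parameters."""


class InsufficientDataError(MonofilmError, ValueError):
    """Raised when an analysis needs more data points than are available."""


class ConfigurationError(MonofilmError, ValueError):
    """Raised for invalid manifests or analysis configurations."""
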