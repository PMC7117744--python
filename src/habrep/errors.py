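"""Exception hierarchy shared across the package."""


class HabrepError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HabrepError, ValueError):
    """Input file does not provide the required columns."""


class IntegrityError(HabrepError, ValueError):
    """Table rows violate a structural invariant (duplicates, inconsistent labels)."""


class ParseError(HabrepError, ValueError):
    """A cell could not be parsed as the expected type."""


class DegenerateDataError(HabrepError, ValueError):
    """Data carry no usable variation (e.g. constant response)."""


class IdentifiabilityError(HabrepError, ValueError):
    """Model cannot be identified from the data (e.g. single-level random factor)."""


class ConvergenceError(HabrepError, RuntimeError):
    """Optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigurationError(HabrepError, ValueError):
    """Invalid analysis configuration (window width, plateau criteria, ...)."""


class SettingsError(HabrepError, ValueError):
    """Invalid resampling settings."""


class ApplicabilityError(HabrepError, ValueError):
    """A statistical procedure does not apply to the given design."""
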