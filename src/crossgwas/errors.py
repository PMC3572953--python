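"""Exception hierarchy shared across the package."""


class CrossGwasError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrossGwasError, ValueError):
    """A simulation or analysis configuration field is invalid."""


class ValidationError(CrossGwasError, ValueError):
    """Input data violates a documented precondition."""


class InsufficientDataError(CrossGwasError, ValueError):
    """Too few observations to compute the requested quantity."""


class HarmonizationError(CrossGwasError, ValueError):
    """Allele pairs of two studies cannot be reconciled."""


class DegenerateFitError(CrossGwasError, RuntimeError):
    """Model fit is degenerate (e.g. constant phenotype, non-PSD kinship)."""
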