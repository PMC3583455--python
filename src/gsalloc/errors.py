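"""Exception types shared across the package."""


class GsallocError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GsallocError, ValueError):
    """A configuration value (genome, budget, model setting) is invalid."""


class InvalidInputError(GsallocError, ValueError):
    """A runtime input (population, phenotype vector, matrix) is invalid."""
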