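"""Exception hierarchy shared across the package."""


class DegrankError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DegrankError, ValueError):
    """Invalid simulation or pipeline configuration."""


class DataError(DegrankError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(DegrankError, ValueError):
    """Input is structurally valid but degenerate for the requested operation."""


class EvaluationError(DegrankError, ValueError):
    """An evaluation metric cannot be computed for the given inputs."""
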