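"""Exception hierarchy used across the package."""


class CoheritError(Exception):
    """Base class for all package errors."""


class ParameterError(CoheritError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class FormatError(CoheritError, ValueError):
    """A file does not conform to the expected on-disk format."""


class TruncationError(FormatError):
    """A binary file is shorter or longer than its header implies."""


class InsufficientDataError(CoheritError, ValueError):
    """Too few samples, cases, or SNPs remain to carry out the operation."""


class ConfigError(CoheritError, ValueError):
    """A pipeline configuration file is invalid or incomplete."""


class ComputationError(CoheritError, RuntimeError):
    """A numerical routine failed (singular system, non-PD covariance, ...)."""
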