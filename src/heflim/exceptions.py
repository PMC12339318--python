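"""Exception hierarchy shared across the package."""


class HeflimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HeflimError, ValueError):
    """A physical or statistical parameter is outside its valid domain."""


class ConfigurationError(HeflimError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class FormatError(HeflimError, IOError):
    """A file does not conform to one of the supported cube/table layouts."""


class EmptyRegionError(HeflimError, ValueError):
    """An operation that needs at least one unmasked pixel received none."""


class NormalizationError(HeflimError, ValueError):
    """Per-sample normalization is impossible (no peritumoral reference)."""


class CalibrationError(HeflimError, ValueError):
    """Phasor calibration reference is degenerate (zero modulus)."""


class UndefinedStatisticError(HeflimError, ValueError):
    """A statistic (mean lifetime, correlation) is undefined for the input."""
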