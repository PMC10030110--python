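"""Exception hierarchy shared by all terrarun modules."""


class TerrarunError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TerrarunError, ValueError):
    """An input object violates one of its declared invariants."""


class TerrainParseError(TerrarunError, ValueError):
    """A terrain grid file could not be parsed; the message names the row."""


class DomainError(TerrarunError, ValueError):
    """A geometric query lies outside the supported domain."""


class ConfigurationError(TerrarunError, ValueError):
    """A configuration value is inconsistent with the data it applies to."""


class CalibrationError(TerrarunError, RuntimeError):
    """Iterative calibration failed to reach its target statistics.

    Carries the statistics achieved at the last iteration in ``achieved``.
    """

    def __init__(self, message, achieved=None):
        super().__init__(message)
        self.achieved = achieved
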