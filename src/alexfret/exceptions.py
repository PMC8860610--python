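"""Exception hierarchy shared across the package."""


class AlexFretError(Exception):
    """Base class for all package errors."""


class FormatError(AlexFretError):
    """A file or record violates the expected on-disk format."""


class MalformedStreamError(AlexFretError):
    """A photon stream violates its invariants (ordering, detector codes)."""


class SimulationError(AlexFretError):
    """A synthetic-data configuration cannot be realized."""


class UndefinedStatisticError(AlexFretError):
    """A statistic was requested on input where it is undefined (e.g. empty table)."""


class UnsupportedDesignError(AlexFretError):
    """The statistical design is outside the supported (balanced, n=3) cases."""


class NormalizationError(AlexFretError):
    """Enhancement normalization is undefined (coincident controls)."""


class CalibrationError(AlexFretError):
    """Ladder calibration failed (degenerate or singular input)."""


class ConfigError(AlexFretError):
    """A run configuration is invalid or incomplete."""
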