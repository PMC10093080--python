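"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad rows, out-of-range values);
``ConfigurationError`` covers inconsistent run configuration; ``CalibrationError``
covers degenerate calibration inputs. The CLI maps validation errors to exit
code 2 and configuration errors to exit code 3.
"""


class DanceMapError(Exception):
    """Base class for all dancemap errors."""


class ValidationError(DanceMapError, ValueError):
    """Invalid input data: bad ranges, malformed rows, inconsistent frames."""


class ConfigurationError(DanceMapError, ValueError):
    """Inconsistent or incomplete run / simulation configuration."""


class CalibrationError(DanceMapError, ValueError):
    """Degenerate calibration input (empty durations, zero estimator value)."""
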